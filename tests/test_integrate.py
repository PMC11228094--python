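"""Platform merging, masking schemes, MAF filtering, year adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pedigen as pg
from pedigen.containers import GenotypeMatrix, make_marker_map
from pedigen.integrate import (MaskScheme, adjust_year_effects,
                               build_masked_dataset, dataset_scheme,
                               filter_maf, masked_cell_count,
                               merge_platforms)


def gm(values, inds, chroms, pos, platform=""):
    mm = make_marker_map([f"m{c}_{p}" for c, p in zip(chroms, pos)],
                         chroms, pos, platform)
    return GenotypeMatrix(np.asarray(values, dtype=np.float32), inds, mm)


class TestMerge:
    def test_printed_panel_sizes_merge_to_printed_total(self):
        """11,152 + 10,899 markers with overlaps pre-removed -> 22,051."""
        nA, nB = 11_152, 10_899
        posA = np.arange(1, nA + 1) * 10
        posB = np.arange(1, nB + 1) * 10 + 5  # disjoint positions
        a = gm(np.zeros((1, nA)), ["x"], ["chr1"] * nA, posA, "A")
        b = gm(np.zeros((1, nB)), ["x"], ["chr1"] * nB, posB, "B")
        merged, report = merge_platforms(a, b)
        assert merged.n_markers == 22_051
        assert report.n_overlap == 0

    def test_identical_single_marker_panels(self):
        a = gm([[1.0], [0.0]], ["x", "y"], ["chr1"], [100], "A")
        b = gm([[1.0], [0.0]], ["x", "y"], ["chr1"], [100], "B")
        merged, report = merge_platforms(a, b)
        assert merged.n_markers == 1
        assert report.n_overlap == 1
        assert report.mean_consistency == pytest.approx(1.0)

    def test_engineered_discordance_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n, m = 40, 60
        base = rng.choice([1.0, 0.0, -1.0], size=(n, m))
        pos = np.arange(1, m + 1) * 1000
        inds = [f"i{k}" for k in range(n)]
        valsA = base.copy()
        valsB = base[:, :9].copy()  # 9 engineered overlap markers
        flip = rng.random(valsB.shape) < 0.02
        valsB[flip] = -valsB[flip] + (valsB[flip] == 0)  # perturb ~2%
        valsA[rng.random(valsA.shape) < 0.05] = np.nan
        a = gm(valsA, inds, ["chr1"] * m, pos, "A")
        b = gm(valsB, inds, ["chr1"] * 9, pos[:9], "B")
        merged, report = merge_platforms(a, b)
        # brute-force per-cell comparison on the shared positions
        cons = []
        for j in range(9):
            x, y = a.values[:, j], b.values[:, j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            cons.append((x[ok] == y[ok]).mean())
        assert report.n_overlap == 9
        assert report.mean_consistency == pytest.approx(np.mean(cons))
        # the higher-missing panel (A) loses its duplicate copies
        assert report.dropped_platform == "A"
        assert merged.n_markers == m

    def test_one_platform_individuals_get_missing(self):
        a = gm([[1.0, 0.0]], ["x"], ["chr1"] * 2, [10, 20], "A")
        b = gm([[-1.0]], ["y"], ["chr1"], [30], "B")
        merged, _ = merge_platforms(a, b)
        assert list(merged.individuals) == ["x", "y"]
        row_y = merged.values[1]
        assert np.isnan(row_y[:2]).all() and row_y[2] == -1.0

    def test_disjoint_chromosome_names_error(self):
        a = gm([[1.0]], ["x"], ["chr1"], [10], "A")
        b = gm([[1.0]], ["x"], ["1"], [10], "B")
        with pytest.raises(ValueError, match="chromosome"):
            merge_platforms(a, b)

    def test_merge_with_empty_panel_is_identity(self, small_pop):
        truth, _, _ = small_pop
        gA = pg.apply_platform(truth, 0)
        gB = pg.apply_platform(truth, 1)
        merged, _ = merge_platforms(gA, gB)
        empty = GenotypeMatrix(np.zeros((0, 0), dtype=np.float32), [],
                               make_marker_map([], [], []))
        again, report = merge_platforms(merged, empty)
        assert np.array_equal(merged.values, again.values, equal_nan=True)
        assert merged.markers.equals(again.markers)


class TestMasking:
    def test_empty_scheme_is_identity(self, small_pop):
        truth, _, _ = small_pop
        merged, _ = pg.merged_observed(truth)
        out = build_masked_dataset(merged, MaskScheme("none", frozenset()))
        assert np.array_equal(out.values, merged.values, equal_nan=True)

    def test_dataset1_masks_platform_b_only(self, small_pop):
        truth, _, design = small_pop
        merged, _ = pg.merged_observed(truth)
        inds, scheme = dataset_scheme(design, 1)
        sub = merged.subset(individuals=inds)
        out = build_masked_dataset(sub, scheme)
        dual = design.offspring_of(design.dual_families)
        rows = [list(out.individuals).index(i) for i in dual]
        colsB = (out.markers["platform"] == "B").values
        assert np.isnan(out.values[np.ix_(rows, colsB)]).all()
        colsA = ~colsB
        assert np.array_equal(out.values[np.ix_(rows, colsA)],
                              sub.values[np.ix_(rows, colsA)],
                              equal_nan=True)

    def test_masked_cell_bookkeeping(self, small_pop):
        """Non-missing cells after masking reconcile with the scheme."""
        truth, _, design = small_pop
        merged, _ = pg.merged_observed(truth)
        for ds in (1, 2, 3):
            inds, scheme = dataset_scheme(design, ds)
            sub = merged.subset(individuals=inds)
            out = build_masked_dataset(sub, scheme)
            row = {i: k for k, i in enumerate(sub.individuals)}
            newly_masked = 0
            for ind, tag in scheme.cells:
                cols = (sub.markers["platform"] == tag).values
                newly_masked += int(
                    (~np.isnan(sub.values[row[ind]][cols])).sum())
            expected = int(np.isnan(sub.values).sum()) + newly_masked
            assert int(np.isnan(out.values).sum()) == expected
            assert masked_cell_count(sub, scheme) >= newly_masked

    def test_unknown_individual_rejected(self, small_pop):
        truth, _, _ = small_pop
        merged, _ = pg.merged_observed(truth)
        scheme = MaskScheme("bad", frozenset({("nobody", "A")}))
        with pytest.raises(KeyError, match="nobody"):
            build_masked_dataset(merged, scheme)


class TestMafFilter:
    def test_zero_threshold_identity(self, small_pop):
        truth, _, _ = small_pop
        g = pg.apply_platform(truth, 0)
        out = filter_maf(g, 0.0)
        assert out.n_markers == g.n_markers

    def test_single_het_among_100_removed(self):
        vals = np.ones((100, 2), dtype=np.float32)
        vals[0, 0] = 0.0  # MAF = 1/200 = 0.005 at marker 0
        vals[:50, 1] = -1.0  # common marker stays
        g = gm(vals, [f"i{k}" for k in range(100)], ["chr1"] * 2, [10, 20])
        out = filter_maf(g, 0.025)
        assert list(out.markers["pos"]) == [20]

    def test_monomorphic_removed_at_any_positive_threshold(self):
        vals = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        g = gm(vals, [f"i{k}" for k in range(20)], ["chr1"] * 2, [10, 20])
        out = filter_maf(g, 1e-9)
        assert list(out.markers["pos"]) == [20]

    def test_all_removed_errors(self):
        g = gm(np.ones((10, 2)), [f"i{k}" for k in range(10)],
               ["chr1"] * 2, [10, 20])
        with pytest.raises(ValueError, match="every marker"):
            filter_maf(g, 0.4)


class TestYearAdjustment:
    def test_single_year_returns_genotype_means(self):
        ph = pd.DataFrame({"individual": ["a", "a", "b"],
                           "year": [2000] * 3, "trait": "t",
                           "value": [1.0, 3.0, 5.0]})
        adj = adjust_year_effects(ph).set_index("individual")["value"]
        assert adj["a"] == pytest.approx(2.0)
        assert adj["b"] == pytest.approx(5.0)

    def test_balanced_design_removes_year_offset(self):
        # closed-form least squares: year 2001 offset +1; adjusted values
        # equal genotype means of the de-offset data
        base = {"a": 1.0, "b": 3.0}
        rows = [(g, y, base[g] + (1.0 if y == 2001 else 0.0))
                for g in "ab" for y in (2000, 2001)]
        ph = pd.DataFrame(rows, columns=["individual", "year", "value"])
        ph["trait"] = "t"
        adj = adjust_year_effects(ph).set_index("individual")["value"]
        # adjusted mean includes the unweighted mean year effect (+0.5)
        assert adj["a"] == pytest.approx(base["a"] + 0.5)
        assert adj["b"] == pytest.approx(base["b"] + 0.5)
        assert adj["b"] - adj["a"] == pytest.approx(2.0)

    def test_constant_shift_equivariance(self):
        rng = np.random.default_rng(0)
        rows = [(f"g{k}", y, rng.normal()) for k in range(6)
                for y in rng.choice([2000, 2001, 2002], 2, replace=False)]
        ph = pd.DataFrame(rows, columns=["individual", "year", "value"])
        ph["trait"] = "t"
        a = adjust_year_effects(ph).set_index("individual")["value"]
        ph2 = ph.assign(value=ph["value"] + 7.0)
        b = adjust_year_effects(ph2).set_index("individual")["value"]
        assert np.allclose(b.values, a.values + 7.0)

    def test_disconnected_design_errors(self):
        ph = pd.DataFrame({"individual": ["a", "a", "b", "b"],
                           "year": [2000, 2001, 2005, 2006],
                           "trait": "t", "value": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="disconnected"):
            adjust_year_effects(ph)

    def test_ranking_preserved_under_additive_year_effects(self, small_pop):
        truth, ped, design = small_pop
        arch = pg.TraitArchitecture(n_qtl=20, additive_var=1.0,
                                    residual_var=0.0,
                                    year_effects={2000: 2.0, 2001: -1.0,
                                                  2002: 0.5})
        ph = pg.simulate_phenotypes(truth, arch, ped, [2000, 2001, 2002],
                                    seed=3, parent_ids=design.parental_ids)
        adj = adjust_year_effects(ph).set_index("individual")["value"]
        genetic = truth.breeding_values.loc[adj.index]
        order_adj = adj.rank()
        order_true = genetic.rank()
        assert (order_adj == order_true).mean() > 0.99


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1))
def test_mask_counts_match_scheme_size(seed):
    rng = np.random.default_rng(seed)
    n, m = 6, 12
    vals = rng.choice([1.0, 0.0, -1.0], size=(n, m)).astype(np.float32)
    tags = rng.choice(["A", "B"], size=m)
    g = GenotypeMatrix(vals, [f"i{k}" for k in range(n)],
                       make_marker_map([f"s{j}" for j in range(m)],
                                       ["chr1"] * m,
                                       np.arange(1, m + 1) * 10, list(tags)))
    inds = rng.choice(list(g.individuals), size=3, replace=False)
    scheme = MaskScheme("x", frozenset((i, "A") for i in inds))
    out = build_masked_dataset(g, scheme)
    assert int(np.isnan(out.values).sum()) == masked_cell_count(g, scheme)
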
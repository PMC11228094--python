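"""Merging genotyping platforms, masking designs, MAF filtering and
year-effect adjustment of phenotypes.

Two marker panels genotyped on the same reference genome are merged by
(chromosome, position).  Markers assayed by both panels ("overlaps") are
reported with their cross-platform genotype consistency and the copy
from the platform with the higher overall missing rate is dropped.

The masking designs reproduce a platform-transition evaluation: a set
of dual-genotyped families has one platform's genotypes hidden so that
family-based imputation can be scored against the hidden calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .simulate import PopulationDesign


@dataclass
class OverlapReport:
    n_overlap: int
    mean_consistency: float  # fraction of agreeing non-missing calls
    dropped_platform: str | None
    per_marker: pd.DataFrame | None = None


@dataclass
class MaskScheme:
    """Cells to hide, at (individual, platform) granularity."""

    label: str
    cells: frozenset  # of (individual_id, platform_tag)

    def individuals(self) -> set[str]:
        return {i for i, _ in self.cells}


# ---------------------------------------------------------------------------
# platform merge

def merge_platforms(genoA: GenotypeMatrix, genoB: GenotypeMatrix
                    ) -> tuple[GenotypeMatrix, OverlapReport]:
    """Merge two platform matrices by physical position.

    Individuals genotyped on only one platform get missing entries for
    the other platform's markers.  At duplicated (chrom, pos) keys the
    copy from the platform with the higher overall missing rate is
    dropped; the report carries the overlap count and the mean genotype
    consistency (fraction of non-missing, agreeing calls) computed
    before removal.
    """
    if genoB.n_markers == 0:
        return genoA.copy(), OverlapReport(0, float("nan"), None)
    _check_chromosomes(genoA.markers, genoB.markers)
    inds = list(genoA.individuals) + [i for i in genoB.individuals
                                      if i not in set(genoA.individuals)]
    rowA = {ind: i for i, ind in enumerate(genoA.individuals)}
    rowB = {ind: i for i, ind in enumerate(genoB.individuals)}
    keyA = list(zip(genoA.markers["chrom"], genoA.markers["pos"]))
    keyB = list(zip(genoB.markers["chrom"], genoB.markers["pos"]))
    shared = set(keyA) & set(keyB)
    missA, missB = genoA.missing_rate(), genoB.missing_rate()
    dropped = None
    per_marker = None
    consistency = float("nan")
    if shared:
        dropped = "A" if missA >= missB else "B"
        both = [i for i in inds if i in rowA and i in rowB]
        ja = {k: j for j, k in enumerate(keyA) if k in shared}
        jb = {k: j for j, k in enumerate(keyB) if k in shared}
        recs = []
        for k in sorted(shared):
            a = genoA.values[[rowA[i] for i in both], ja[k]]
            b = genoB.values[[rowB[i] for i in both], jb[k]]
            ok = ~np.isnan(a) & ~np.isnan(b)
            cons = float((a[ok] == b[ok]).mean()) if ok.any() else np.nan
            recs.append((k[0], k[1], int(ok.sum()), cons))
        per_marker = pd.DataFrame(
            recs, columns=["chrom", "pos", "n_compared", "consistency"])
        consistency = float(per_marker["consistency"].mean())
    keepA = np.ones(genoA.n_markers, dtype=bool)
    keepB = np.ones(genoB.n_markers, dtype=bool)
    if dropped == "A":
        keepA = np.array([k not in shared for k in keyA])
    elif dropped == "B":
        keepB = np.array([k not in shared for k in keyB])
    mm = pd.concat([genoA.markers.loc[keepA], genoB.markers.loc[keepB]],
                   ignore_index=True)
    order = mm.sort_values(["chrom", "pos"], kind="mergesort").index.values
    mm = mm.iloc[order].reset_index(drop=True)
    n, m = len(inds), len(mm)
    vals = np.full((n, m), np.nan, dtype=np.float32)
    nA = int(keepA.sum())
    colmap = np.empty(m, dtype=np.int64)  # merged col -> source col
    src_is_A = order < nA
    idxA = np.flatnonzero(keepA)
    idxB = np.flatnonzero(keepB)
    for j, oj in enumerate(order):
        colmap[j] = idxA[oj] if oj < nA else idxB[oj - nA]
    ra = np.array([rowA.get(i, -1) for i in inds])
    rb = np.array([rowB.get(i, -1) for i in inds])
    colsA = np.flatnonzero(src_is_A)
    colsB = np.flatnonzero(~src_is_A)
    okA = ra >= 0
    okB = rb >= 0
    vals[np.ix_(okA, colsA)] = genoA.values[np.ix_(ra[okA], colmap[colsA])]
    vals[np.ix_(okB, colsB)] = genoB.values[np.ix_(rb[okB], colmap[colsB])]
    merged = GenotypeMatrix(vals, inds, mm)
    report = OverlapReport(len(shared), consistency, dropped, per_marker)
    return merged, report


def _check_chromosomes(mmA: pd.DataFrame, mmB: pd.DataFrame) -> None:
    ca, cb = set(mmA["chrom"]), set(mmB["chrom"])
    if ca and cb and not (ca & cb):
        raise ValueError(
            "conflicting chromosome naming between platforms; unmatched: "
            f"{sorted(ca)[:5]} vs {sorted(cb)[:5]}")


# ---------------------------------------------------------------------------
# masking designs

def build_masked_dataset(merged: GenotypeMatrix, scheme: MaskScheme
                         ) -> GenotypeMatrix:
    """Set every cell named by the scheme to missing; all else untouched."""
    out = merged.copy()
    if not scheme.cells:
        return out
    bad_inds = scheme.individuals() - set(merged.individuals)
    if bad_inds:
        raise KeyError(f"scheme names unknown individuals: {sorted(bad_inds)[:5]}")
    tags = set(merged.markers["platform"])
    row = {ind: i for i, ind in enumerate(merged.individuals)}
    for tag in {t for _, t in scheme.cells}:
        if tag not in tags:
            raise KeyError(f"scheme names unknown platform {tag!r}")
        cols = (merged.markers["platform"] == tag).values
        rows = [row[i] for i, t in scheme.cells if t == tag]
        out.values[np.ix_(rows, cols)] = np.nan
    return out


def masked_cell_count(merged: GenotypeMatrix, scheme: MaskScheme) -> int:
    counts = merged.markers["platform"].value_counts()
    return int(sum(counts.get(t, 0) for _, t in scheme.cells))


def dataset_scheme(design: PopulationDesign, dataset: int,
                   platform_tags: tuple[str, str] = ("A", "B")
                   ) -> tuple[list[str], MaskScheme]:
    """Individuals and mask for the three evaluation datasets.

    Platform tag "A" is the incumbent array panel, tag "B" the newly
    introduced amplicon assay.

    * Dataset 1: parents + dual-genotyped families; the families'
      platform-B genotypes are masked.
    * Dataset 2: same individuals; the families' platform-A genotypes
      are masked.
    * Dataset 3: parents + all families; dual families have platform A
      masked (their amplicon data is new), array-only families carry
      no platform-B data at all.
    """
    tagA, tagB = platform_tags
    dual = design.offspring_of(design.dual_families)
    if dataset in (1, 2):
        inds = list(design.parental_ids) + dual
        tag = tagB if dataset == 1 else tagA
        cells = frozenset((i, tag) for i in dual)
    elif dataset == 3:
        single = design.offspring_of(design.single_families)
        inds = list(design.parental_ids) + dual + single
        cells = frozenset((i, tagA) for i in dual) | \
            frozenset((i, tagB) for i in single)
    else:
        raise ValueError("dataset must be 1, 2 or 3")
    return inds, MaskScheme(f"Dataset {dataset}", cells)


# ---------------------------------------------------------------------------
# MAF filter

def filter_maf(geno: GenotypeMatrix, threshold: float
               ) -> GenotypeMatrix:
    """Drop markers whose minor-allele frequency (non-missing calls) is
    below ``threshold``.  Markers with no calls at all are dropped for
    any threshold > 0."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    if threshold == 0.0:
        return geno.copy()
    maf = geno.maf()
    keep = ~np.isnan(maf) & (maf >= threshold)
    if not keep.any():
        raise ValueError("MAF filter removed every marker")
    return geno.subset(marker_mask=keep)


# ---------------------------------------------------------------------------
# year-effect adjustment

def adjust_year_effects(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Adjust repeated phenotype records for year effects.

    Fits, per trait, the additive two-way fixed-effect model
    ``value ~ genotype + year`` by least squares and reports one
    adjusted value per genotype: intercept + genotype effect + the
    unweighted mean of the year effects (an effects-style adjusted
    mean, appropriate for unbalanced multi-year trial data).
    """
    out = []
    for trait, grp in phenotypes.groupby("trait", sort=False):
        out.append(_adjust_one_trait(grp, trait))
    return pd.concat(out, ignore_index=True)


def _adjust_one_trait(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    genos = pd.Index(pd.unique(df["individual"]))
    years = np.sort(pd.unique(df["year"]))
    if len(years) == 1:
        adj = df.groupby("individual", sort=False)["value"].mean()
        return pd.DataFrame({"individual": adj.index, "trait": trait,
                             "value": adj.values})
    _check_connected(df)
    gi = genos.get_indexer(df["individual"])
    yi = np.searchsorted(years, df["year"])
    n = len(df)
    G, Y = len(genos), len(years)
    # treatment coding: intercept, genotype 2..G, year 2..Y
    X = np.zeros((n, 1 + (G - 1) + (Y - 1)))
    X[:, 0] = 1.0
    mask_g = gi > 0
    X[np.flatnonzero(mask_g), gi[mask_g]] = 1.0
    mask_y = yi > 0
    X[np.flatnonzero(mask_y), G + yi[mask_y] - 1] = 1.0
    beta, *_ = np.linalg.lstsq(X, df["value"].to_numpy(float), rcond=None)
    g_eff = np.concatenate([[0.0], beta[1:G]])
    y_eff = np.concatenate([[0.0], beta[G:]])
    adjusted = beta[0] + g_eff + y_eff.mean()
    return pd.DataFrame({"individual": genos, "trait": trait,
                         "value": adjusted})


def _check_connected(df: pd.DataFrame) -> None:
    g = nx.Graph()
    for ind, yr in zip(df["individual"], df["year"]):
        g.add_edge(("g", ind), ("y", int(yr)))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        blocks = [sorted(x[1] for x in c if x[0] == "g")[:4] for c in comps]
        raise ValueError(
            f"genotype x year design is disconnected; blocks: {blocks}")
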
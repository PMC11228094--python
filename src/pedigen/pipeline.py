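"""End-to-end evaluation pipelines on simulated populations.

`evaluate_imputation` reproduces the masking-based accuracy design for
platform transitions: merge the two platform matrices, hide one
platform's genotypes for the dual-genotyped families (Datasets 1-3),
re-impute them by family phasing, and score the imputed genotypes and
parental-phase assignments against the simulator's ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree
from .integrate import build_masked_dataset, dataset_scheme, merge_platforms
from .phasing import (AccuracyReport, estimate_parental_origin, phase_family,
                      phasing_accuracy, score_accuracy)
from .simulate import PopulationDesign, TruthSet, apply_platform


def merged_observed(truth: TruthSet) -> tuple[GenotypeMatrix, object]:
    """Observed two-platform matrices merged into one panel."""
    gA = apply_platform(truth, 0)
    gB = apply_platform(truth, 1)
    return merge_platforms(gA, gB)


def evaluate_imputation(truth: TruthSet, pedigree: Pedigree,
                        design: PopulationDesign, dataset: int,
                        window: int = 30, reps: int = 100, seed: int = 0,
                        label_by_voting: bool = True,
                        parent_haps: str = "observed") -> AccuracyReport:
    """Mask, re-impute and score one evaluation dataset.

    Offspring of the dual-genotyped families are phased against their
    parents' haplotypes with the origin DP, the masked platform's
    genotypes are imputed from the origin mosaic, and two metrics are
    returned: score accuracy (imputed = true dosage over masked cells)
    and phasing accuracy (maternal-assignment concordance at
    heterozygous markers).  Parental-origin labels are assigned by the
    window-correlation voting algorithm when ``label_by_voting``.

    With ``parent_haps="observed"`` (default) a parent's haplotype
    alleles are unknown (NaN) wherever its own merged genotype call is
    missing: the pipeline performs no population-LD imputation, so
    parental missingness propagates into unimputable offspring cells
    (which score as errors).  ``parent_haps="true"`` uses the complete
    simulated parental phases instead.
    """
    merged, _ = merged_observed(truth)
    inds, scheme = dataset_scheme(design, dataset)
    sub = merged.subset(individuals=inds)
    masked = build_masked_dataset(sub, scheme)
    # merged marker column -> truth marker column, keyed by marker id
    truth_col = {m: j for j, m in enumerate(truth.marker_map["id"])}
    cols = np.array([truth_col[m] for m in masked.markers["id"]])
    tags_of = {}
    for ind, tag in scheme.cells:
        tags_of.setdefault(ind, set()).add(tag)
    row = {ind: i for i, ind in enumerate(masked.individuals)}
    rng = np.random.default_rng([seed, 11])
    fam_rows = []
    n_correct = n_masked = n_unimputed = 0
    phase_accs = []
    for fam_id in design.dual_families:
        fam = design.families.set_index("family_id").loc[fam_id]
        dam, sire = fam["dam"], fam["sire"]
        mhap = truth.haplotypes[truth.row(dam)][:, cols].astype(float)
        phap = truth.haplotypes[truth.row(sire)][:, cols].astype(float)
        if parent_haps == "observed":
            for hap, parent in ((mhap, dam), (phap, sire)):
                holes = np.isnan(masked.values[row[parent]])
                hap[:, holes] = np.nan
        elif parent_haps != "true":
            raise ValueError("parent_haps must be 'observed' or 'true'")
        fam_correct = fam_masked = 0
        fam_phase = []
        for kid in design.members[fam_id]:
            i = row[kid]
            obs = masked.values[i].astype(float)
            phase = phase_family(mhap, phap, obs, masked.markers)
            mask = np.zeros(masked.n_markers, dtype=bool)
            for tag in tags_of.get(kid, ()):
                mask |= (masked.markers["platform"] == tag).values
            true_row = truth.genotypes()[truth.row(kid)][cols]
            if mask.any():
                imputed, unk = _impute(phase, mhap, phap, mask)
                acc_cells = (~np.isnan(imputed)) & (imputed == true_row) & mask
                fam_correct += int(acc_cells.sum())
                fam_masked += int(mask.sum())
                n_unimputed += unk
            est_m, est_p = phase.haplotypes
            if label_by_voting:
                label, _votes = estimate_parental_origin(
                    est_m, mhap, phap, masked.markers, n_markers=window,
                    reps=reps, seed=rng)
                if label == "male":
                    est_m, est_p = est_p, est_m
            true_m = truth.haplotypes[truth.row(kid), 0][cols]
            het = true_row == 0
            if mask.any():  # score the re-created platform's phases
                het = het & mask
            pa = phasing_accuracy(est_m, true_m, het)
            if pa is not None:
                fam_phase.append(pa)
                phase_accs.append(pa)
        n_correct += fam_correct
        n_masked += fam_masked
        fam_rows.append((fam_id, fam_correct / fam_masked if fam_masked else
                         np.nan, float(np.mean(fam_phase)) if fam_phase
                         else np.nan, fam_masked))
    per_family = pd.DataFrame(
        fam_rows, columns=["family_id", "score_accuracy", "phasing_accuracy",
                           "n_masked"])
    score = n_correct / n_masked if n_masked else float("nan")
    phase_acc = float(np.mean(phase_accs)) if phase_accs else float("nan")
    return AccuracyReport(phase_acc, score, per_family, n_masked, n_unimputed)


def _impute(phase, mhap, phap, mask):
    from .phasing import impute_from_origin

    return impute_from_origin(phase.origin, mhap, phap, mask)
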
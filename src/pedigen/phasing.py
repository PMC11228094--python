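"""Family-based phasing, parental-origin assignment and imputation.

Offspring genotypes are phased against their two phased parents by a
dynamic program over the four parental-origin states (which maternal
haplotype x which paternal haplotype), minimizing genotype mismatches
under a crossover penalty.  The resulting origin mosaic imputes any
masked or missing markers as the sum of the copied parental alleles.

Parental-origin labels of a haplotype can also be estimated by the
window-correlation voting algorithm: repeatedly draw a short window of
consecutive markers, correlate it against all four parental haplotypes,
and let each repetition vote for the parent owning the best-correlated
haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

#: cost of one crossover in the phasing DP, in units of one genotype
#: mismatch; 2.5 makes a single crossover cheaper than three isolated
#: mismatches but dearer than two.
CROSSOVER_PENALTY = 2.5

MENDEL_WARN_FRACTION = 0.05


@dataclass
class FamilyPhase:
    """Phased offspring haplotypes with their parental-origin mosaic.

    ``haplotypes[0]`` is the maternally inherited haplotype (alleles
    copied from the mother), ``haplotypes[1]`` the paternal one.
    ``origin[g, m]`` is which of parent g's two haplotypes gamete g
    copies at marker m.
    """

    haplotypes: np.ndarray  # (2, M) float; NaN = unknown parental allele
    origin: np.ndarray  # (2, M) int8
    n_breakpoints: int
    mendel_error_rate: float
    mendel_flagged: bool
    mismatch_markers: np.ndarray  # indices where phased sum != observed


@dataclass
class AccuracyReport:
    phasing_accuracy: float
    score_accuracy: float
    per_family: pd.DataFrame
    n_masked_cells: int = 0
    n_unimputed: int = 0


# ---------------------------------------------------------------------------
# phasing DP

def phase_family(mother_haps: np.ndarray, father_haps: np.ndarray,
                 offspring_geno: np.ndarray, marker_map: pd.DataFrame,
                 crossover_penalty: float = CROSSOVER_PENALTY) -> FamilyPhase:
    """Phase one offspring against its phased parents.

    Parameters
    ----------
    mother_haps, father_haps
        (2, M) arrays of haplotype alleles (0/1) over the marker map.
    offspring_geno
        (M,) dosages in {1, 0, -1} with NaN for missing calls.
    """
    M = len(marker_map)
    if mother_haps.shape != (2, M) or father_haps.shape != (2, M):
        raise ValueError("parent haplotypes do not match the marker map")
    mother_haps = np.asarray(mother_haps, dtype=float)
    father_haps = np.asarray(father_haps, dtype=float)
    obs = np.asarray(offspring_geno, dtype=float) + 1.0  # 0/1/2 allele count
    # expected allele count per state (a, b): mother[a] + father[b];
    # NaN parental alleles (unobserved in the parent) are uninformative
    expect = np.empty((4, M))
    for s, (a, b) in enumerate(_STATES):
        expect[s] = mother_haps[a] + father_haps[b]
    observed = ~np.isnan(obs)
    known = ~np.isnan(expect)
    mismatch = np.zeros((4, M))
    cmp_mask = known & observed[None, :]
    mismatch[cmp_mask] = np.abs((expect - obs)[cmp_mask])
    # a half-mismatch keeps states with an unknown parental allele neutral
    mismatch[~known & observed[None, :]] = 0.5
    impossible = observed & known.all(axis=0) \
        & (np.where(known, mismatch, np.inf).min(axis=0) > 0.0)
    mendel_rate = float(impossible.sum() / max(observed.sum(), 1))
    flagged = mendel_rate > MENDEL_WARN_FRACTION
    if flagged:
        warnings.warn(
            f"{mendel_rate:.1%} of observed markers are Mendelian-"
            "impossible for the given parents; treating them as missing",
            stacklevel=2)
    mismatch[:, impossible] = 0.0
    state = np.empty(M, dtype=np.int8)
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        sl = slice(int(grp.index[0]), int(grp.index[-1]) + 1)
        path = _viterbi(mismatch[:, sl], crossover_penalty)
        state[sl] = _center_switches(path, mismatch[:, sl])
    a = _STATE_A[state]
    b = _STATE_B[state]
    ar = np.arange(M)
    hap0 = mother_haps[a, ar]
    hap1 = father_haps[b, ar]
    origin = np.stack([a, b]).astype(np.int8)
    chrom_codes = pd.factorize(marker_map["chrom"])[0]
    same_chrom = chrom_codes[1:] == chrom_codes[:-1]
    breaks = int(((a[1:] != a[:-1]) & same_chrom).sum()
                 + ((b[1:] != b[:-1]) & same_chrom).sum())
    phased_sum = hap0 + hap1
    bad = observed & ~np.isnan(phased_sum) & (phased_sum != obs)
    return FamilyPhase(np.stack([hap0, hap1]), origin,
                       breaks, mendel_rate, flagged, np.flatnonzero(bad))


_STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]
_STATE_A = np.array([a for a, _ in _STATES])
_STATE_B = np.array([b for _, b in _STATES])
# switches between states: number of haplotype changes (0, 1 or 2)
_NSWITCH = np.array([[bin((_STATE_A[i] != _STATE_A[j])
                          + 2 * (_STATE_B[i] != _STATE_B[j])).count("1")
                      for j in range(4)] for i in range(4)], dtype=float)


def _viterbi(cost: np.ndarray, penalty: float) -> np.ndarray:
    """Minimum-cost state path over one chromosome (4 origin states)."""
    n = cost.shape[1]
    trans = penalty * _NSWITCH
    score = cost[:, 0].copy()
    back = np.zeros((n, 4), dtype=np.int8)
    for m in range(1, n):
        step = score[:, None] + trans  # prev state x next state
        back[m] = np.argmin(step, axis=0)
        score = step[back[m], np.arange(4)] + cost[:, m]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmin(score))
    for m in range(n - 1, 0, -1):
        path[m - 1] = back[m, path[m]]
    return path


def _center_switches(path: np.ndarray, cost: np.ndarray) -> np.ndarray:
    """Re-place each state switch at the midpoint of its cost-indifferent
    interval.

    Viterbi ties put a crossover at an arbitrary edge of the stretch of
    markers that cannot distinguish the two flanking states; centring
    the breakpoint minimizes the expected number of misassigned
    markers when the true crossover is uniform over the gap.
    """
    n = len(path)
    switches = np.flatnonzero(path[1:] != path[:-1]) + 1
    out = path.copy()
    lo_bound = 0
    for k, t in enumerate(switches):
        s_prev, s_next = path[t - 1], path[t]
        hi_bound = switches[k + 1] if k + 1 < len(switches) else n
        a = t
        while a - 1 >= lo_bound and cost[s_next, a - 1] == cost[s_prev, a - 1]:
            a -= 1
        b = t
        while b < hi_bound and cost[s_prev, b] == cost[s_next, b]:
            b += 1
        mid = (a + b) // 2
        out[a:mid] = s_prev
        out[mid:b] = s_next
        lo_bound = t
    return out


# ---------------------------------------------------------------------------
# window-correlation voting

def estimate_parental_origin(offspring_hap: np.ndarray,
                             mother_haps: np.ndarray,
                             father_haps: np.ndarray,
                             marker_map: pd.DataFrame,
                             n_markers: int = 30, reps: int = 100,
                             seed: int | np.random.Generator = 0
                             ) -> tuple[str, dict[str, int]]:
    """Vote on which parent transmitted a haplotype.

    Each repetition draws a window of ``n_markers`` consecutive markers
    (within one chromosome), computes the Pearson correlation between
    the offspring haplotype window and each of the four parental
    haplotype windows, and votes for the parent owning the best-
    correlated haplotype.  The final label is the majority parent;
    an exact tie yields ``"unknown"``.

    Windows in which the offspring haplotype is monomorphic (zero
    variance, correlation undefined) are discarded and redrawn, up to
    ``10 * reps`` attempts in total.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng([seed, 7])
    chrom_bounds = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        lo, hi = int(grp.index[0]), int(grp.index[-1]) + 1
        if hi - lo >= n_markers:
            chrom_bounds.append((lo, hi))
    if not chrom_bounds:
        raise ValueError(f"no chromosome carries >= {n_markers} markers")
    parents = np.stack([mother_haps[0], mother_haps[1],
                        father_haps[0], father_haps[1]]).astype(float)
    child = np.asarray(offspring_hap, dtype=float)
    votes = {"female": 0, "male": 0}
    cast = 0
    for _ in range(10 * reps):
        if cast >= reps:
            break
        lo, hi = chrom_bounds[int(rng.integers(0, len(chrom_bounds)))]
        start = int(rng.integers(lo, hi - n_markers + 1))
        w = slice(start, start + n_markers)
        cw = child[w]
        if not np.isfinite(cw).all() or cw.std() == 0.0:
            continue
        pw = parents[:, w]
        ps = pw.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = ((pw - pw.mean(axis=1, keepdims=True))
                    @ (cw - cw.mean())) / (n_markers * ps * cw.std())
        corr = np.where(np.isnan(corr), -np.inf, corr)
        if not np.isfinite(corr).any():
            continue
        best_f = corr[:2].max()
        best_m = corr[2:].max()
        if best_f == best_m:
            continue  # uninformative draw
        votes["female" if best_f > best_m else "male"] += 1
        cast += 1
    if votes["female"] == votes["male"]:
        return "unknown", votes
    return ("female" if votes["female"] > votes["male"] else "male"), votes


# ---------------------------------------------------------------------------
# imputation and accuracy

def impute_from_origin(origin: np.ndarray, mother_haps: np.ndarray,
                       father_haps: np.ndarray, mask: np.ndarray
                       ) -> tuple[np.ndarray, int]:
    """Impute masked dosages from the origin mosaic.

    Returns the imputed (M,) dosage vector ({1,0,-1}, NaN where the
    origin is unknown) restricted to ``mask`` positions, plus the count
    of masked markers left missing because the origin was unknown.
    """
    M = origin.shape[1]
    ar = np.arange(M)
    mother_haps = np.asarray(mother_haps, dtype=float)
    father_haps = np.asarray(father_haps, dtype=float)
    known = (origin[0] >= 0) & (origin[1] >= 0)
    out = np.full(M, np.nan)
    o0 = np.clip(origin[0], 0, 1)
    o1 = np.clip(origin[1], 0, 1)
    vals = mother_haps[o0, ar] + father_haps[o1, ar] - 1.0
    out[known] = vals[known]
    n_unknown = int((mask & (~known | np.isnan(out))).sum())
    result = np.full(M, np.nan)
    result[mask] = out[mask]
    return result, n_unknown


def score_accuracy(imputed: np.ndarray, truth: np.ndarray,
                   mask: np.ndarray) -> float:
    """Fraction of masked cells whose imputed {1,0,-1} score equals the
    truth; missing imputations count as errors."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    imp = np.asarray(imputed, dtype=float)[..., :]
    tru = np.asarray(truth, dtype=float)
    ok = ~np.isnan(imp) & (imp == tru)
    return float((ok & mask).sum() / mask.sum())


def phasing_accuracy(est_maternal_hap: np.ndarray,
                     true_maternal_hap: np.ndarray,
                     het_mask: np.ndarray) -> float | None:
    """Concordance of the female-parent-labeled haplotype with the truly
    maternally transmitted allele at heterozygous markers.

    Returns None for individuals with no heterozygous markers.
    """
    het_mask = np.asarray(het_mask, dtype=bool)
    if het_mask.sum() == 0:
        return None
    return float((est_maternal_hap[het_mask]
                  == true_maternal_hap[het_mask]).mean())
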
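"""Inbreeding coefficients and runs of homozygosity (ROH).

Pedigree inbreeding comes from the tabular additive-relationship
recursion (F = A_ii - 1, founders assumed non-inbred).  Genomic
inbreeding F_ROH is the fraction of the SNP-covered genome inside ROH
detected by the consecutive-SNP method: scan each chromosome and emit
every maximal stretch of markers whose heterozygote and missing-call
counts stay within per-run budgets and whose inter-marker gaps stay
below a ceiling, subject to minimum SNP-count and physical-length
thresholds.  ROH islands are genome regions where an exceptionally
high share of individuals carry a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree

RUN_COLUMNS = ["individual", "chrom", "start", "end", "n_snps", "length"]


@dataclass
class ROHParams:
    """Consecutive-SNP ROH detection parameters.

    Defaults follow common practice for ~20k-SNP panels: runs of at
    least 100 SNPs and 1 Mb, at most one heterozygous and one missing
    call per run, and no gap above 1 Mb between consecutive run SNPs.
    """

    min_snp: int = 100
    max_gap: int = 1_000_000
    min_length: int = 1_000_000
    max_opp_run: int = 1
    max_miss_run: int = 1

    def validate(self) -> None:
        if min(self.min_snp, self.max_gap, self.min_length,
               self.max_opp_run, self.max_miss_run) < 0:
            raise ValueError("all ROH parameters must be >= 0")


# ---------------------------------------------------------------------------
# pedigree inbreeding

def additive_relationship(pedigree: Pedigree) -> pd.DataFrame:
    """Wright's numerator relationship matrix A by the tabular method."""
    inds = pedigree.individuals
    n = len(inds)
    idx = {ind: i for i, ind in enumerate(inds)}
    A = np.zeros((n, n))
    for i, (_, rec) in enumerate(pedigree.table.iterrows()):
        s, d = rec["sire"], rec["dam"]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        if si is None and di is None:
            A[i, i] = 1.0
        else:
            row = np.zeros(i)
            if si is not None:
                row += 0.5 * A[si, :i]
            if di is not None:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + (0.5 * A[si, di]
                             if si is not None and di is not None else 0.0)
    return pd.DataFrame(A, index=inds, columns=inds)


def pedigree_inbreeding(pedigree: Pedigree) -> pd.Series:
    """Pedigree inbreeding coefficients F = A_ii - 1 (founders F = 0)."""
    A = additive_relationship(pedigree)
    f = pd.Series(np.diag(A.values) - 1.0, index=A.index, name="F_pedigree")
    return f.loc[pedigree.individuals]


def inbreeding_table(pedigree: Pedigree, f_roh: pd.Series) -> pd.DataFrame:
    """Combine pedigree and ROH inbreeding with the pedigree's years."""
    t = pedigree.table.set_index("individual")
    out = pd.DataFrame({
        "F_pedigree": pedigree_inbreeding(pedigree),
        "F_roh": f_roh.reindex(t.index),
        "crossing_year": t["crossing_year"],
        "registration_year": t["registration_year"],
    })
    return out


# ---------------------------------------------------------------------------
# ROH detection

def detect_roh(geno_row: np.ndarray, marker_map: pd.DataFrame,
               params: ROHParams | None = None,
               individual: str = "") -> pd.DataFrame:
    """Detect ROH in one individual by the consecutive-SNP method.

    Emits every maximal window of consecutive markers satisfying the
    heterozygote/missing budgets and the gap ceiling, then filters on
    ``min_snp`` and ``min_length``.  Runs never span chromosomes.
    Start/end are the base-pair positions of the first/last SNP in the
    run; length = end - start + 1.
    """
    params = params or ROHParams()
    params.validate()
    geno_row = np.asarray(geno_row, dtype=float)
    runs = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"marker map not sorted on {chrom}")
        sl = slice(int(grp.index[0]), int(grp.index[-1]) + 1)
        g = geno_row[sl]
        het = (g == 0.0)
        mis = np.isnan(g)
        # split the chromosome at gaps exceeding the ceiling
        splits = np.flatnonzero(np.diff(pos) > params.max_gap) + 1
        for seg in np.split(np.arange(len(pos)), splits):
            runs.extend(_maximal_windows(pos[seg], het[seg], mis[seg],
                                         params, chrom))
    df = pd.DataFrame(runs, columns=RUN_COLUMNS[1:])
    df.insert(0, "individual", individual)
    return df


def _maximal_windows(pos, het, mis, params: ROHParams, chrom) -> list:
    """All maximal budget-feasible windows in one gap-free segment."""
    n = len(pos)
    out = []
    r = 0
    nh = nm = 0
    prev_r = -1
    for l in range(n):
        if r < l:
            r, nh, nm = l, 0, 0
        while r < n and nh + het[r] <= params.max_opp_run \
                and nm + mis[r] <= params.max_miss_run:
            nh += het[r]
            nm += mis[r]
            r += 1
        if r > prev_r:  # maximal: not contained in the previous window
            nsnp = r - l
            length = int(pos[r - 1] - pos[l] + 1)
            if nsnp >= params.min_snp and length >= params.min_length:
                out.append((chrom, int(pos[l]), int(pos[r - 1]), nsnp, length))
            prev_r = r
        nh -= het[l]
        nm -= mis[l]
    return out


def detect_roh_all(geno: GenotypeMatrix, params: ROHParams | None = None
                   ) -> pd.DataFrame:
    """ROH runs for every individual of a genotype matrix."""
    frames = [detect_roh(geno.values[i], geno.markers, params, ind)
              for i, ind in enumerate(geno.individuals)]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# genomic inbreeding

def froh(runs: pd.DataFrame, marker_map: pd.DataFrame,
         individuals=None) -> pd.Series:
    """F_ROH: union length of an individual's runs over the SNP-covered
    genome (sum over chromosomes of last - first SNP position + 1).

    Overlapping runs are unioned so no base pair is counted twice.
    """
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    denom = 0
    for _, grp in marker_map.groupby("chrom", sort=False):
        denom += int(grp["pos"].max() - grp["pos"].min() + 1)
    if individuals is None:
        individuals = pd.unique(runs["individual"])
    out = {}
    for ind in individuals:
        sub = runs.loc[runs["individual"] == ind]
        total = 0
        for _, grp in sub.groupby("chrom", sort=False):
            ivs = sorted(zip(grp["start"], grp["end"]))
            cur_s, cur_e = None, None
            for s, e in ivs:
                if cur_e is None or s > cur_e + 1:
                    if cur_e is not None:
                        total += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s + 1
        out[ind] = total / denom
    return pd.Series(out, name="F_roh")


# ---------------------------------------------------------------------------
# ROH islands

@dataclass
class ROHIslandSet:
    incidence: pd.Series  # % of individuals covered, aligned to the map
    threshold: float  # incidence percentile cut (percent)
    islands: pd.DataFrame  # chrom, start, end, n_snps, peak_incidence


def roh_islands(all_runs: pd.DataFrame, marker_map: pd.DataFrame,
                n_individuals: int, top_pct: float = 15.0) -> ROHIslandSet:
    """Call ROH islands from the per-SNP run incidence.

    Incidence is the percentage of individuals whose ROH covers each
    SNP; the island threshold is the (100 - top_pct) percentile of the
    incidences over all SNPs, and islands are maximal consecutive-SNP
    intervals at or above it.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    cover = np.zeros(len(marker_map))
    pos_by_chrom = {c: (grp["pos"].to_numpy(np.int64), int(grp.index[0]))
                    for c, grp in marker_map.groupby("chrom", sort=False)}
    for ind, sub in all_runs.groupby("individual", sort=False):
        covered = np.zeros(len(marker_map), dtype=bool)
        for _, r in sub.iterrows():
            pos, off = pos_by_chrom[r["chrom"]]
            lo = np.searchsorted(pos, r["start"], side="left")
            hi = np.searchsorted(pos, r["end"], side="right")
            covered[off + lo: off + hi] = True
        cover += covered
    incidence = pd.Series(100.0 * cover / n_individuals,
                          index=marker_map["id"], name="incidence")
    threshold = float(np.percentile(incidence.values, 100.0 - top_pct))
    hot = incidence.values >= threshold
    rows = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        sl = slice(int(grp.index[0]), int(grp.index[-1]) + 1)
        h = hot[sl]
        pos = grp["pos"].to_numpy(np.int64)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], h.view(np.int8),
                                                       [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            rows.append((chrom, int(pos[s]), int(pos[e - 1]), int(e - s),
                         float(incidence.values[sl][s:e].max())))
    islands = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "peak_incidence"])
    return ROHIslandSet(incidence, threshold, islands)


# ---------------------------------------------------------------------------
# BED export

def runs_to_bed(runs: pd.DataFrame, path) -> None:
    """Write runs as BED (0-based half-open) with the individual as name."""
    with open(path, "w") as fh:
        for _, r in runs.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t"
                     f"{r.get('individual', '.')}\n")


def islands_to_bed(islands: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for k, r in islands.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t"
                     f"island{k}\t{r['peak_incidence']:.1f}\n")
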
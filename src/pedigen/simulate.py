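"""Synthetic pedigreed breeding populations with two-platform genotyping.

The generator emulates the structure of a clonal fruit-tree breeding
program: a parental population built by repeatedly crossing a small set
of founders (so inbreeding rises over generations), plus many full-sib
F1 families derived from a subset of the parents.  A small number of
families are genotyped on both marker platforms; the rest on one only.
Ground truth (haplotypes, gamete origin paths, founder-allele ancestry,
QTL effects, breeding values) is retained for accuracy evaluation.

Haplotype alleles are internally coded {0, 1}; observed dosages use the
{1, 0, -1} = {AA, Aa, aa} convention of :mod:`pedigen.containers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree, make_marker_map

PLATFORM_TAGS = ("A", "B")  # A ~ incumbent array panel, B ~ new amplicon panel


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic breeding population.

    Defaults are a desk-scale rendition (roughly 1/10) of a breeding
    program with ~184 parents and ~207 full-sib families genotyped on an
    ~11k-SNP array panel (platform A) and an ~11k-SNP amplicon panel
    (platform B) over 17 chromosomes, with a 9-marker overlap between
    panels and platform missing-call rates of 0.005 and 0.016.
    """

    n_founders: int = 12
    n_parent_generations: int = 2
    n_families: int = 20
    family_size_range: tuple[int, int] = (6, 14)
    n_dual_families: int = 3
    n_chromosomes: int = 17
    chrom_length_bp: int = 30_000_000
    markers_per_platform: tuple[int, int] = (1100, 1050)
    overlap_markers: int = 9
    missing_rate: tuple[float, float] = (0.005, 0.016)
    recomb_rate: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_founders, self.n_families, self.n_chromosomes,
                  self.chrom_length_bp, *self.markers_per_platform,
                  self.family_size_range[0], self.family_size_range[1]]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_parent_generations < 0 or self.overlap_markers < 0:
            raise ValueError("generations and overlap must be >= 0")
        if not all(0.0 <= r <= 1.0 for r in self.missing_rate):
            raise ValueError("missing rates must lie in [0, 1]")
        if self.overlap_markers > min(self.markers_per_platform):
            raise ValueError("overlap_markers exceeds a platform's size")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if not 0 < self.n_dual_families <= self.n_families:
            raise ValueError("n_dual_families must be in 1..n_families")


@dataclass
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    ``inbreeding_effect_b`` is the directional-dominance (inbreeding
    depression) parameter: the fixed regression of phenotype on the
    individual's true genomic inbreeding F, in phenotype units per unit
    of F.
    """

    n_qtl: int = 50
    additive_var: float = 1.0
    dominance_var: float = 0.0
    inbreeding_effect_b: float = 0.0
    year_effects: dict[int, float] = field(default_factory=dict)
    residual_var: float = 1.0

    def validate(self) -> None:
        if min(self.additive_var, self.dominance_var, self.residual_var) < 0:
            raise ValueError("variances must be >= 0")
        if self.n_qtl <= 0:
            raise ValueError("n_qtl must be positive")


@dataclass
class PopulationDesign:
    """Which individuals play which role in the breeding program."""

    parental_ids: list[str]
    families: pd.DataFrame  # family_id, sire, dam, size, dual
    members: dict[str, list[str]]  # family_id -> offspring ids

    @property
    def dual_families(self) -> list[str]:
        return self.families.loc[self.families["dual"], "family_id"].tolist()

    @property
    def single_families(self) -> list[str]:
        return self.families.loc[~self.families["dual"], "family_id"].tolist()

    def offspring_of(self, family_ids) -> list[str]:
        return [i for f in family_ids for i in self.members[f]]


class TruthSet:
    """Complete simulated ground truth for one population.

    Attributes
    ----------
    marker_map : pandas.DataFrame
        Union marker map over both platforms; ``platform`` is "A", "B"
        or "both".
    individuals : list of str
    haplotypes : int8 array, shape (n, 2, M)
        Allele (0/1) carried by each of the two haplotypes.  Haplotype 0
        is the maternally inherited gamete, haplotype 1 the paternal.
    ancestry : int32 array, shape (n, 2, M)
        Founder-gamete label each allele descends from; autozygosity is
        equality of the two labels.
    origin : int8 array, shape (n, 2, M)
        For non-founders: which of the parent's two haplotypes (0/1) the
        gamete copies at each marker; -1 for founders.
    """

    def __init__(self, marker_map, individuals, haplotypes, ancestry, origin,
                 config: SimConfig):
        self.marker_map = marker_map
        self.individuals = list(individuals)
        self.haplotypes = haplotypes
        self.ancestry = ancestry
        self.origin = origin
        self.config = config
        self.qtl: pd.DataFrame | None = None
        self.breeding_values: pd.Series | None = None
        self._index = {ind: i for i, ind in enumerate(self.individuals)}

    def row(self, individual: str) -> int:
        return self._index[individual]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def genotypes(self) -> np.ndarray:
        """True dosages {1,0,-1}: sum of haplotype alleles minus 1."""
        return self.haplotypes.sum(axis=1).astype(np.int8) - 1

    def true_inbreeding(self) -> pd.Series:
        """Fraction of markers autozygous by descent, per individual."""
        f = (self.ancestry[:, 0, :] == self.ancestry[:, 1, :]).mean(axis=1)
        return pd.Series(f, index=self.individuals, name="F_true")

    def chrom_slices(self) -> dict:
        out, mm = {}, self.marker_map
        for chrom, grp in mm.groupby("chrom", sort=False):
            out[chrom] = slice(int(grp.index[0]), int(grp.index[-1]) + 1)
        return out


# ---------------------------------------------------------------------------
# pedigree generation

def generate_pedigree(config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Pedigree, PopulationDesign]:
    """Build a breeding-program pedigree with preferential parent reuse.

    A handful of "elite" founders receive high crossing weights, so that
    later generations accumulate inbreeding, mimicking programs in which
    a few superior cultivars are used repeatedly as parents.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng([config.seed, 1])
    records = []
    founders = [f"F{i:03d}" for i in range(config.n_founders)]
    for i, f in enumerate(founders):
        records.append((f, None, None, 1935 + i % 5, 1940 + i % 5))
    pool = list(founders)
    # elite weighting: geometric decay over the pool, renormalized as it grows
    weights = list(0.6 ** np.arange(config.n_founders))
    for g in range(1, config.n_parent_generations + 1):
        newcomers = []
        for j in range(config.n_founders):
            w = np.asarray(weights) / np.sum(weights)
            sire, dam = _draw_pair(rng, pool, w)
            ind = f"P{g}_{j:03d}"
            year = 1940 + 15 * g + int(rng.integers(0, 6))
            records.append((ind, sire, dam, year, year + 5))
            newcomers.append(ind)
        pool.extend(newcomers)
        weights.extend(0.3 * 0.8 ** np.arange(len(newcomers)))
    parental_ids = list(pool)
    fam_rows, members = [], {}
    lo, hi = config.family_size_range
    for k in range(config.n_families):
        w = np.asarray(weights) / np.sum(weights)
        sire, dam = _draw_pair(rng, pool, w)
        fam = f"FAM{k:03d}"
        size = int(rng.integers(lo, hi + 1))
        year = 1990 + int(rng.integers(0, 25))
        kids = [f"{fam}_{m:03d}" for m in range(size)]
        for kid in kids:
            records.append((kid, sire, dam, year, year + 5))
        fam_rows.append((fam, sire, dam, size, k < config.n_dual_families))
        members[fam] = kids
    ped = Pedigree(pd.DataFrame(
        records, columns=["individual", "sire", "dam",
                          "crossing_year", "registration_year"]))
    fams = pd.DataFrame(fam_rows,
                        columns=["family_id", "sire", "dam", "size", "dual"])
    return ped, PopulationDesign(parental_ids, fams, members)


def _draw_pair(rng, pool, weights):
    i = rng.choice(len(pool), p=weights)
    j = rng.choice(len(pool), p=weights)
    while j == i and len(pool) > 1:
        j = rng.choice(len(pool), p=weights)
    return pool[i], pool[j]


# ---------------------------------------------------------------------------
# founders and gene dropping

def simulate_founders(config: SimConfig,
                      pedigree: Pedigree | None = None) -> TruthSet:
    """Draw the marker map and founder haplotypes.

    Per-marker allele frequencies are uniform on [0.05, 0.95]; founder
    haplotype alleles are independent Bernoulli draws at those
    frequencies (founders unrelated, linkage equilibrium).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    mm = _simulate_marker_map(config, rng)
    founders = pedigree.founders if pedigree is not None \
        else [f"F{i:03d}" for i in range(config.n_founders)]
    n, M = len(founders), len(mm)
    freq = rng.uniform(0.05, 0.95, size=M)
    haps = (rng.random((n, 2, M)) < freq).astype(np.int8)
    ancestry = np.arange(2 * n, dtype=np.int32).reshape(n, 2, 1)
    ancestry = np.broadcast_to(ancestry, (n, 2, M)).copy()
    origin = np.full((n, 2, M), -1, dtype=np.int8)
    return TruthSet(mm, founders, haps, ancestry, origin, config)


def _simulate_marker_map(config: SimConfig, rng) -> pd.DataFrame:
    cA, cB = config.markers_per_platform
    total = cA + cB - config.overlap_markers
    # spread markers over chromosomes proportionally to (equal) lengths
    base = total // config.n_chromosomes
    counts = np.full(config.n_chromosomes, base)
    counts[: total - base * config.n_chromosomes] += 1
    chroms, poss = [], []
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1, dtype=np.int64),
            size=counts[c], replace=False))
        chroms.extend([f"chr{c + 1:02d}"] * counts[c])
        poss.extend(pos.tolist())
    tags = np.array(["A"] * (cA - config.overlap_markers)
                    + ["B"] * (cB - config.overlap_markers)
                    + ["both"] * config.overlap_markers)
    rng.shuffle(tags)
    ids = [f"m{i:05d}" for i in range(total)]
    return make_marker_map(ids, chroms, poss, list(tags))


def drop_gametes(pedigree: Pedigree, founder_truth: TruthSet,
                 config: SimConfig) -> TruthSet:
    """Gene-drop haplotypes through the pedigree.

    Meiosis model: per chromosome, crossover count ~ Poisson(recomb_rate),
    breakpoint positions uniform on the chromosome, no interference; the
    starting parental haplotype of each gamete is a fair coin.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    mm = founder_truth.marker_map
    M = len(mm)
    inds = pedigree.individuals
    n = len(inds)
    haps = np.zeros((n, 2, M), dtype=np.int8)
    ancestry = np.zeros((n, 2, M), dtype=np.int32)
    origin = np.full((n, 2, M), -1, dtype=np.int8)
    index = {ind: i for i, ind in enumerate(inds)}
    chrom_pos = [(sl, mm["pos"].values[sl]) for sl in
                 _chrom_slices(mm).values()]
    frow = {ind: founder_truth.row(ind) for ind in founder_truth.individuals}
    for _, rec in pedigree.table.iterrows():
        ind, sire, dam = rec["individual"], rec["sire"], rec["dam"]
        i = index[ind]
        if sire is None and dam is None:
            if ind not in frow:
                raise KeyError(f"founder {ind!r} absent from founder truth")
            j = frow[ind]
            haps[i] = founder_truth.haplotypes[j]
            ancestry[i] = founder_truth.ancestry[j]
            continue
        if sire is None or dam is None:
            raise ValueError(f"{ind!r} has exactly one known parent; "
                             "single-parent records are not supported")
        for g, parent in enumerate((dam, sire)):  # hap 0 maternal, 1 paternal
            if parent not in index:
                raise KeyError(f"unknown parent id {parent!r}")
            p = index[parent]
            path = _meiosis_path(rng, chrom_pos, M, config.recomb_rate)
            ar = np.arange(M)
            haps[i, g] = haps[p, path, ar]
            ancestry[i, g] = ancestry[p, path, ar]
            origin[i, g] = path
    return TruthSet(mm, inds, haps, ancestry, origin, config)


def _chrom_slices(mm: pd.DataFrame) -> dict:
    out = {}
    for chrom, grp in mm.groupby("chrom", sort=False):
        out[chrom] = slice(int(grp.index[0]), int(grp.index[-1]) + 1)
    return out


def _meiosis_path(rng, chrom_pos, M, recomb_rate) -> np.ndarray:
    path = np.empty(M, dtype=np.int8)
    for sl, pos in chrom_pos:
        start = int(rng.integers(0, 2))
        k = rng.poisson(recomb_rate)
        if k == 0 or len(pos) == 0:
            path[sl] = start
            continue
        length = int(pos[-1]) if len(pos) else 1
        bp = np.sort(rng.uniform(0, length, size=k))
        # parity of crossovers to the left of each marker
        flips = np.searchsorted(bp, pos, side="left") % 2
        path[sl] = (start + flips) % 2
    return path


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(truth: TruthSet, architecture: TraitArchitecture,
                        pedigree: Pedigree, years: list[int], seed: int,
                        trait: str = "trait",
                        parent_ids: list[str] | None = None) -> pd.DataFrame:
    """Simulate phenotype records y = additive + dominance + b*F + year + e.

    Additive and dominance components are sums over QTL, rescaled so
    their empirical population variances equal the architecture's
    ``additive_var`` / ``dominance_var``.  ``F`` is the true genomic
    inbreeding (autozygous marker fraction).  Parents (``parent_ids``)
    are observed in several of the given years, offspring in one —
    reproducing the unbalanced repeated-measures design of long-running
    cultivar trials.

    Returns a table (individual, year, trait, value) and attaches
    ``truth.qtl`` and ``truth.breeding_values``.
    """
    architecture.validate()
    rng = np.random.default_rng([seed, 4])
    M = truth.n_markers
    if architecture.n_qtl > M:
        raise ValueError("more QTL than markers")
    qtl_idx = np.sort(rng.choice(M, size=architecture.n_qtl, replace=False))
    dose = truth.genotypes()[:, qtl_idx].astype(float) + 1.0  # 0/1/2
    het = (dose == 1.0).astype(float)
    a_eff = rng.normal(size=architecture.n_qtl)
    d_eff = rng.normal(size=architecture.n_qtl)
    add = dose @ a_eff
    dom = het @ d_eff
    add = _rescale(add, architecture.additive_var)
    dom = _rescale(dom, architecture.dominance_var)
    f_true = truth.true_inbreeding().values
    genetic = add + dom + architecture.inbreeding_effect_b * f_true
    truth.qtl = pd.DataFrame({
        "marker_index": qtl_idx,
        "marker_id": truth.marker_map["id"].values[qtl_idx],
        "additive_effect": a_eff, "dominance_effect": d_eff})
    truth.breeding_values = pd.Series(add, index=truth.individuals,
                                      name="breeding_value")
    parent_ids = set(parent_ids or [])
    rows = []
    sd_e = float(np.sqrt(architecture.residual_var))
    for i, ind in enumerate(truth.individuals):
        if ind in parent_ids and len(years) > 1:
            k = int(rng.integers(1, len(years) + 1))
            obs_years = sorted(rng.choice(years, size=k, replace=False))
        else:
            obs_years = [years[int(rng.integers(0, len(years)))]]
        for y in obs_years:
            val = (genetic[i] + architecture.year_effects.get(int(y), 0.0)
                   + rng.normal(0.0, sd_e))
            rows.append((ind, int(y), trait, val))
    return pd.DataFrame(rows, columns=["individual", "year", "trait", "value"])


def _rescale(x: np.ndarray, target_var: float) -> np.ndarray:
    if target_var == 0.0:
        return np.zeros_like(x)
    s = x.std()
    if s == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) * np.sqrt(target_var) / s


# ---------------------------------------------------------------------------
# observed platforms

def apply_platform(truth: TruthSet, platform_index: int,
                   config: SimConfig | None = None) -> GenotypeMatrix:
    """Extract one platform's observed genotype matrix from the truth.

    Restricts to the platform's marker subset (its own markers plus the
    overlap markers shared by both platforms), codes dosages {1,0,-1}
    for AA/Aa/aa and knocks out calls at the platform's missing rate.
    """
    config = config or truth.config
    if platform_index not in (0, 1):
        raise ValueError("platform_index must be 0 or 1")
    tag = PLATFORM_TAGS[platform_index]
    mask = truth.marker_map["platform"].isin([tag, "both"]).values
    vals = truth.genotypes()[:, mask].astype(np.float32)
    rate = config.missing_rate[platform_index]
    if rate > 0:
        rng = np.random.default_rng([config.seed, 100 + platform_index])
        vals[rng.random(vals.shape) < rate] = np.nan
    mm = truth.marker_map.loc[mask].reset_index(drop=True).copy()
    mm["platform"] = tag
    return GenotypeMatrix(vals, truth.individuals, mm)


def simulate_population(config: SimConfig
                        ) -> tuple[TruthSet, Pedigree, PopulationDesign]:
    """Convenience wrapper: pedigree + founders + gene drop in one call."""
    ped, design = generate_pedigree(config)
    founders = simulate_founders(config, ped)
    truth = drop_gametes(ped, founders, config)
    return truth, ped, design
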
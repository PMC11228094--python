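"""Shared data containers: marker maps, dosage matrices and pedigrees.

Dosage coding follows the breeding-genetics convention used throughout the
package: ``1`` = AA (homozygous reference), ``0`` = Aa (heterozygous),
``-1`` = aa (homozygous alternate); missing calls are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MAP_COLUMNS = ["id", "chrom", "pos", "platform"]

#: dosage code -> count of reference alleles
DOSAGE_TO_COUNT = {1: 2, 0: 1, -1: 0}


def make_marker_map(
    ids: Sequence[str],
    chrom: Sequence,
    pos: Sequence[int],
    platform: Sequence[str] | str = "",
) -> pd.DataFrame:
    """Build a marker map table sorted by (chromosome, position).

    Positions are 1-based base-pair coordinates on a shared reference
    genome; merging of genotyping platforms keys on (chrom, pos).
    """
    if isinstance(platform, str):
        platform = [platform] * len(ids)
    mm = pd.DataFrame(
        {"id": list(ids), "chrom": list(chrom), "pos": np.asarray(pos, dtype=np.int64),
         "platform": list(platform)}
    )
    mm = mm.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return mm


def validate_marker_map(mm: pd.DataFrame, require_unique: bool = True) -> None:
    missing = [c for c in MAP_COLUMNS if c not in mm.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    key = mm[["chrom", "pos"]]
    if not (key.sort_values(["chrom", "pos"]).index == key.index).all():
        raise ValueError("marker map must be sorted by (chrom, pos)")
    if require_unique and key.duplicated().any():
        dup = mm.loc[key.duplicated(), ["chrom", "pos"]]
        raise ValueError(f"duplicated marker positions: {dup.values.tolist()[:5]}")


class GenotypeMatrix:
    """Individuals x markers dosage matrix tied to a marker map.

    Parameters
    ----------
    values
        Array of shape (n_individuals, n_markers) with entries in
        {1, 0, -1} and NaN for missing calls.
    individuals
        Individual identifiers (row labels).
    markers
        Marker map with columns id / chrom / pos / platform, sorted by
        (chrom, pos) and aligned to the columns of ``values``.
    """

    def __init__(self, values: np.ndarray, individuals: Sequence[str],
                 markers: pd.DataFrame):
        values = np.asarray(values, dtype=np.float32)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (individuals x markers)")
        if values.shape[0] != len(individuals):
            raise ValueError("row count does not match individual list")
        if values.shape[1] != len(markers):
            raise ValueError("column count does not match marker map")
        validate_marker_map(markers, require_unique=False)
        self.values = values
        self.individuals = pd.Index(individuals, name="individual")
        self.markers = markers.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values.copy(), self.individuals.copy(),
                              self.markers.copy())

    def missing_rate(self) -> float:
        return float(np.isnan(self.values).mean())

    def dosage012(self) -> np.ndarray:
        """Return reference-allele counts (0/1/2) with NaN preserved."""
        return self.values + 1.0

    def allele_freq(self) -> np.ndarray:
        """Per-marker reference-allele frequency on non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage012(), axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting -------------------------------------------------------
    def subset(self, individuals: Iterable[str] | None = None,
               marker_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        vals, inds, mm = self.values, self.individuals, self.markers
        if individuals is not None:
            idx = inds.get_indexer(list(individuals))
            if (idx < 0).any():
                missing = [i for i, j in zip(individuals, idx) if j < 0]
                raise KeyError(f"unknown individuals: {missing[:5]}")
            vals = vals[idx]
            inds = pd.Index(list(individuals), name="individual")
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask)
            vals = vals[:, marker_mask]
            mm = mm.loc[marker_mask].reset_index(drop=True) if marker_mask.dtype == bool \
                else mm.iloc[marker_mask].reset_index(drop=True)
        return GenotypeMatrix(vals.copy(), inds, mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals,
                            columns=self.markers["id"])


@dataclass
class PedigreeRecord:
    individual: str
    sire: str | None
    dam: str | None
    crossing_year: int | None = None
    registration_year: int | None = None


class Pedigree:
    """Acyclic pedigree; iteration order is topological (parents first)."""

    def __init__(self, records: Iterable[PedigreeRecord] | pd.DataFrame):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
            for col in ("crossing_year", "registration_year"):
                if col not in df.columns:
                    df[col] = None
        else:
            df = pd.DataFrame([r.__dict__ for r in records])
        df["sire"] = df["sire"].where(pd.notna(df["sire"]), None)
        df["dam"] = df["dam"].where(pd.notna(df["dam"]), None)
        if df["individual"].duplicated().any():
            dup = df.loc[df["individual"].duplicated(), "individual"].tolist()
            raise ValueError(f"duplicate individuals in pedigree: {dup[:5]}")
        ids = set(df["individual"])
        for col in ("sire", "dam"):
            unknown = [p for p in df[col] if p is not None and p not in ids]
            if unknown:
                raise ValueError(f"unknown parent id(s): {sorted(set(unknown))[:5]}")
        g = nx.DiGraph()
        g.add_nodes_from(df["individual"])
        for _, r in df.iterrows():
            for p in (r["sire"], r["dam"]):
                if p is not None:
                    g.add_edge(p, r["individual"])
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cycle}")
        df = df.set_index("individual").loc[order].reset_index()
        self.table = df
        self._graph = g

    @property
    def individuals(self) -> list[str]:
        return self.table["individual"].tolist()

    @property
    def founders(self) -> list[str]:
        t = self.table
        mask = t["sire"].isna() & t["dam"].isna()
        return t.loc[mask, "individual"].tolist()

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        row = self.table.set_index("individual").loc[individual]
        return (row["sire"] if pd.notna(row["sire"]) else None,
                row["dam"] if pd.notna(row["dam"]) else None)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, individual: str) -> bool:
        return individual in self._graph

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path))
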
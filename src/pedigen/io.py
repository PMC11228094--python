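"""Reading and writing genotypes (VCF, dosage TSV) and phenotypes (CSV).

VCF writing targets plain-text VCF 4.2 with GT-only records; reading
goes through cyvcf2 and accepts anything htslib can parse.  Dosage
matrices are marker-by-individual TSV with id/chrom/pos/platform lead
columns, matching the in-memory {1, 0, -1, NA} coding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, make_marker_map

_GT_UNPHASED = {2: "0/0", 1: "0/1", 0: "1/1"}
# haplotype allele 1 is the reference 'A' -> VCF allele index 0
_GT_PHASED = {(1, 1): "0|0", (1, 0): "0|1", (0, 1): "1|0", (0, 0): "1|1"}


def write_vcf(geno: GenotypeMatrix, path, haplotypes: np.ndarray | None = None
              ) -> None:
    """Write a genotype matrix as an uncompressed VCF.

    The reference allele is the 'A' allele of the {1,0,-1} coding (so
    dosage 1 = 0/0).  If ``haplotypes`` (n, 2, M with alleles 0/1 coding
    the *reference* allele as 1) is given, GT fields are phased with
    '|' separators; otherwise genotypes are unphased.
    """
    mm = geno.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedigen\n")
        for chrom in mm["chrom"].unique():
            ln = int(mm.loc[mm["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={ln + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individuals) + "\n")
        vals = geno.values
        for j in range(geno.n_markers):
            row = mm.iloc[j]
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      "A", "C", ".", "PASS", ".", "GT"]
            if haplotypes is None:
                gts = ["./." if np.isnan(v) else _GT_UNPHASED[int(v) + 1]
                       for v in vals[:, j]]
            else:
                # haplotype allele 1 == reference 'A' -> VCF allele index 0
                gts = [_GT_PHASED[(int(haplotypes[i, 0, j]),
                                   int(haplotypes[i, 1, j]))]
                       for i in range(geno.n_individuals)]
            fh.write("\t".join(fields + gts) + "\n")


def read_vcf(path, platform: str = "") -> GenotypeMatrix:
    """Read a VCF into the {1,0,-1,NaN} dosage coding (REF treated as 'A')."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = np.array([1.0, 0.0, np.nan, -1.0])
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(code[var.gt_types])
    vcf.close()
    mm = make_marker_map(ids, chroms, poss, platform)
    vals = np.asarray(rows, dtype=np.float32).T
    # make_marker_map sorts; realign columns to the sorted map
    pos_of = {m: k for k, m in enumerate(ids)}
    cols = [pos_of[m] for m in mm["id"]]
    return GenotypeMatrix(vals[:, cols], individuals, mm)


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = geno.markers.copy()
    body = pd.DataFrame(geno.values.T, columns=geno.individuals)
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False,
                                         na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    lead = [c for c in ("id", "chrom", "pos", "platform") if c in df.columns]
    inds = [c for c in df.columns if c not in lead]
    mm = make_marker_map(df["id"], df["chrom"], df["pos"],
                         df["platform"] if "platform" in df else "")
    pos_of = {m: k for k, m in enumerate(df["id"])}
    cols = [pos_of[m] for m in mm["id"]]
    vals = df[inds].to_numpy(dtype=np.float32).T[:, cols]
    return GenotypeMatrix(vals, inds, mm)


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(config, path) -> None:
    """Key/value text dump of a SimConfig-like dataclass."""
    with open(path, "w") as fh:
        for k, v in vars(config).items():
            fh.write(f"{k} = {v!r}\n")
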
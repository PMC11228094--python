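# pedigen

Quantitative genetics of pedigreed breeding populations whose genotypes
come from **two different genotyping platforms** — the situation a
long-running fruit-tree breeding program faces when it switches, say,
from a SNP array to an amplicon-sequencing assay. The package covers
the full analysis chain:

* **Simulation** of a breeding population (founders, a parental
  population built by repeated crossing of a few elite parents, full-sib
  F1 families) with two marker panels, complete ground truth, and traits
  with additive, dominance, inbreeding-depression and year components.
* **Platform merging** by physical position, with overlap-consistency
  reporting, masking designs for imputation benchmarking, MAF filtering,
  and year-effect adjustment of multi-year trial phenotypes.
* **Family-based phasing and imputation**: a dynamic program over the
  four parental-origin states phases each offspring against its phased
  parents; hidden platform genotypes are imputed from the origin mosaic;
  parental-origin labels can be assigned by window-correlation voting.
* **Inbreeding**: pedigree F (tabular relationship matrix, F = A_ii − 1),
  runs of homozygosity by the consecutive-SNP method, genomic F_ROH, and
  ROH islands (top-15% per-SNP incidence).
* **LMM GWAS**: single-SNP P3D/EMMAX tests and sliding SNP-set kernel
  tests, both corrected by a genomic kinship matrix and principal
  components, with Benjamini–Hochberg FDR.
* **Genomic prediction**: GBLUP with additive (VanRaden *G*) and
  dominance kernels and a *directional* inbreeding effect — the fixed
  regression *b* of phenotype on the genomic inbreeding coefficient
  (inbreeding depression) — plus a training-scenario evaluation for the
  platform-transition setting.

## The core models

Phenotypes are modelled as

y = Xβ + b·F + u + (d) + e,  u ~ N(0, σ²ₐ G), d ~ N(0, σ²_d D), e ~ N(0, σ²ₑ I)

with G = WWᵀ / 2Σpₖ(1−pₖ) the VanRaden genomic relationship matrix on
centred dosages, D the heterozygosity-coded dominance matrix, and F the
per-individual genomic inbreeding coefficient (F_ROH). All variance
components are estimated by REML (spectral decomposition for one
kernel, numerical ratio search for several). GWAS tests each SNP by
generalized least squares at the null variance components (P3D), and
each 41-SNP window (window half-size 20, slide 1) through a
window-specific random effect with a linear kernel, using the
variance-component score statistic with its exact
ratio-of-quadratic-forms null.

## A worked example

```bash
python examples/03_phase_and_impute.py
```

```
dataset  masked platform   score acc   phasing acc
   1     B (amplicon)      0.923       0.953
   2     A (array)         0.941       0.959
   3     A (array)         0.941       0.959
```

Three evaluation datasets mimic a platform transition: the
dual-genotyped families have one panel hidden and re-imputed from
their parents. *Score accuracy* is the fraction of hidden dosages
imputed exactly; *phasing accuracy* is the concordance of the
maternal-haplotype assignment at heterozygous hidden markers. Dataset 1
(hide the amplicon panel, whose missing rate is ~3× the array's) is
hardest, because family-based imputation inherits the parents' missing
calls on the hidden panel. `examples/` contains one script per
capability (simulation, merging, phasing, ROH, GWAS, prediction, year
adjustment), each printing the numbers it computes and what they mean.

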
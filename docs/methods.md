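# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Population and genotype simulation

The generator (`pedigen.simulate`) emulates a clonal-crop breeding
program. `n_founders` unrelated founders carry haplotypes drawn
marker-by-marker from Bernoulli(p) with p ~ U(0.05, 0.95) (linkage
equilibrium). A parental population is built over
`n_parent_generations` waves of crosses in which a geometric "elite"
weighting makes a few individuals recurrent parents — this, not
selection, is what drives inbreeding upward over generations, the
pattern observed in real breeding pedigrees. `n_families` full-sib F1
families are then produced from elite-weighted parental pairs; the
first `n_dual_families` are dual-genotyped on both platforms, the rest
on the array panel only.

Meiosis uses a Poisson crossover count per chromosome (mean
`recomb_rate`, default 1.5), uniform breakpoint positions and no
interference. Each gamete's per-marker parental-origin path and the
founder-gamete ancestry of every allele are recorded, so true genomic
inbreeding is exact: F_true = fraction of markers where the two
alleles descend from the same founder gamete.

Two marker panels share one coordinate system: platform A (array,
1,100 markers, missing rate 0.005) and platform B (amplicon, 1,050
markers, 0.016), with 9 markers assayed by both. The default scale is
roughly one tenth of a real two-panel program (~11k + ~11k SNPs, 184
parents, 207 families); defaults were chosen for desk-scale runtime
and are stated in `SimConfig`. Missingness is the only genotyping-error
process modelled; a call-error hook is deliberately absent (default
error rate zero), which matters for interpreting the imputation
benchmark below.

Phenotypes: y = Σ additive QTL effects + Σ dominance deviations +
b·F_true + year effect + residual. Component variances are set by
*empirical rescaling* — the simulated additive and dominance sums are
scaled so their population variances equal the requested values — so
"20% QTL variance" is exact in every replicate. b is the directional
inbreeding-depression parameter in phenotype units per unit F. Parents
are observed in several (unbalanced) years, offspring in one,
mimicking long-running cultivar trials.

## Platform merging and the evaluation datasets

Merging keys on (chromosome, position), 1-based, alleles ignored. At a
duplicated position the copy from the platform with the higher overall
missing rate is dropped; the report carries the overlap count and the
mean fraction of agreeing non-missing calls ("genotype consistency")
computed before removal. Individuals genotyped on one platform get
missing entries for the other's markers.

Three masked datasets reproduce a platform-transition benchmark on the
dual-genotyped families: Dataset 1 hides their amplicon (B) genotypes,
Datasets 2 and 3 hide their array (A) genotypes; Dataset 3 adds the
array-only families (which carry no B data at all). Evaluation always
scores the hidden platform of the dual families against the simulation
truth.

Year adjustment fits the additive two-way fixed-effects model
value ~ genotype + year by least squares and reports, per genotype,
intercept + genotype effect + the unweighted mean of year effects (an
effects-style adjusted mean, appropriate for unbalanced data). A
disconnected genotype×year design is rejected with the offending
blocks named.

## Family phasing, origin voting and imputation

Each offspring is phased against its two phased parents by a Viterbi
dynamic program over the four origin states (which maternal haplotype
× which paternal haplotype). The emission cost is the absolute
difference between expected and observed allele count (so a
double mismatch costs 2); a state switch costs 2.5 per gamete, making
one crossover cheaper than three isolated mismatches but dearer than
two — tuned to typical genotyping-error vs recombination rates.
Because Viterbi ties otherwise pile breakpoints at the edge of
uninformative stretches, each inferred switch is re-placed at the
midpoint of its cost-indifferent marker interval, which minimizes the
expected number of misassigned markers when the true crossover is
uniform over the gap. Markers impossible under all four states are
Mendelian errors; above 5% of observed markers a warning is raised and
they are treated as missing.

Parental-origin labels can also be estimated by window-correlation
voting: repeatedly draw 30 consecutive markers within a chromosome,
correlate the offspring haplotype window against all four parental
haplotype windows, and let each repetition vote for the parent owning
the best-correlated haplotype (100 repetitions; monomorphic windows
redrawn, exact final ties labelled unknown). The window length is in
markers, not base pairs — at realistic densities a base-pair window
this small would almost never contain two markers. Windows are drawn
per chromosome on allele (0/1) coding.

Imputation copies the parents' alleles along the origin mosaic. In the
dataset evaluation the parents' haplotypes are their true phases *with
holes wherever the parent's own merged genotype call is missing*: the
pipeline performs no population-LD imputation (out of scope by
design), so an offspring cell whose transmitted parental allele is
unobserved stays missing and scores as an error. This is the mechanism
behind the Dataset ordering: hiding the amplicon panel (Dataset 1) is
hardest because that panel's ~3× higher missing rate leaves more holes
in the parents. Phasing accuracy is evaluated at heterozygous markers
of the hidden platform — the re-created content — as maternal-
assignment concordance; that metric has no standard definition, and
this is ours. At the default desk-scale density (~126 markers per
chromosome) crossover localization is ambiguous over a few markers, so
score accuracy plateaus near 0.94–0.95; at 10× density the same
algorithm's intrinsic error shrinks roughly tenfold. Passing tests
therefore demonstrate correctness of the mechanism, not the accuracy a
dense real panel would achieve. No genotype-call errors are simulated,
so platform-quality effects beyond missingness are absent from the
benchmark.

## Inbreeding and ROH

Pedigree inbreeding comes from the tabular relationship matrix
(F = A_ii − 1) with founders assumed non-inbred; this reproduces the
known downward bias of pedigree F when founder inbreeding is
unrecorded, visible in the simulation as F_ROH > F_pedigree on
average.

ROH detection is the consecutive-SNP method: every *maximal* window of
consecutive markers containing at most `max_opp_run` heterozygous and
`max_miss_run` missing calls, with no inter-marker gap above
`max_gap`, at least `min_snp` markers and `min_length` bp. Budgets are
per run, gaps are checked between consecutive run markers, and runs
never span chromosomes. With positive budgets two maximal runs can
overlap; F_ROH uses the union of an individual's runs (no base pair
counted twice) over the SNP-covered genome (per chromosome, last −
first marker position + 1). The default parameters (100 SNPs / 1 Mb /
1 Mb gap / 1 het / 1 missing) suit ~20k-SNP genome-wide panels; the
desk-scale analyses in the examples and the acceptance script use
min_snp = 15 at the same physical thresholds, matching the 10× lower
marker density. Islands: per-SNP incidence = % of individuals whose
run covers the SNP; the threshold is the 85th percentile of incidence
over *all* SNPs (zeros included); islands are maximal consecutive-SNP
intervals at or above it.

## GWAS

Kinship is the VanRaden G on mean-imputed dosages; structure
correction adds the top 3 genotype principal components as fixed
covariates; markers below MAF 0.025 are excluded. The null LMM is
fitted by REML via one spectral decomposition and a bracketed 1-D
search over the variance ratio. Single-SNP tests are P3D/EMMAX:
variance components fixed at the null fit, per-SNP GLS Wald t-tests
(the per-SNP exact-REML refit is the test oracle, agreeing within 0.2
−log10 units). Collinear SNPs get p = 1 and a flag.

The SNP-set test slides a window of focal ± 20 SNPs (41 mid-
chromosome, truncated at ends). After whitening by the null
covariance, the window's standardized genotypes form a linear kernel
and the variance-component *score* statistic is referred to its exact
finite-sample null — a ratio of quadratic forms whose tail probability
is computed by Imhof integration over the kernel's eigenvalues. We use
the score test rather than the restricted LRT with the asymptotic
0.5·χ²₀ + 0.5·χ²₁ boundary mixture because at 41-SNP windows the
mixture is badly conservative (the underlying statistic is a skewed
41-term χ² mixture, far from the asymptotic regime); the LRT variant
remains available as `method="lrt"`. Null calibration is verified
under traits drawn from the model itself (polygenic background from
the kinship, h² = 0.5): under a zero-background null, the boundary
REML estimate of the variance ratio noise-fits and visibly deflates
every window statistic — a property of all P3D-style pipelines, worth
remembering when interpreting set-test p-values on traits with little
genetic signal. Significance uses Benjamini–Hochberg FDR at 0.05 per
trait, windows and SNPs separately.

The power comparison between the two tests uses a linkage-equilibrium
founder panel with eight causal SNPs dispersed in one window, each
individually sub-threshold and with mixed effect signs. Two findings
shaped this design: in a family population the long-range LD lets a
single SNP tag any within-window combination, so the single-SNP scan
essentially always matches the windowed test; and with only five
sub-threshold effects the windowed statistic's 41-dof baseline penalty
leaves it at or below the genome-wide single-SNP minimum even in
linkage equilibrium. Aggregation wins reliably once the number of
small dispersed effects reaches about eight.

## Genomic prediction

Kernels: VanRaden G and the heterozygosity-coded dominance matrix
D = HHᵀ/Σ(2pq)², H = 1{het} − 2pq, each stabilized by +1e-6 on the
diagonal. Models A, A+F, A+D, A+D+F, with F (marker-based inbreeding)
as a fixed covariate whose coefficient b is the inbreeding-depression
parameter; a constant F column is dropped with a warning. Estimation
is REML throughout — deterministic, no sampler tuning — rather than a
Bayesian sampler; the estimands (variance components, b, BLUPs) are
the same in expectation. Single-kernel fits use the spectral path;
two-kernel fits optimize the two variance ratios by Nelder–Mead from
three starts. BLUPs are computed for all individuals in the kernel,
phenotyped or not, so hold-out prediction is Xβ + Σ u_k.

The training-scenario evaluation holds out the dual-genotyped families
throughout: Train 1 = parents at amplicon-panel markers only, Train 2
= parents at the merged panel, Train 3 = parents + all non-test
families at the merged panel (test families excluded from training to
avoid leakage). Accuracy is Pearson r between predictions and
phenotypes on the hold-out set, clamped at zero, plus RMSE; the
improvement rate from adding the inbreeding term is r_with/r_without
and RMSE_without/RMSE_with (>1 = better on both scales). An estimated
inbreeding effect projects onto descendants as
child_effect × (1/2)^(generations−1).

## Problem sizes and reproducibility

All stochastic components accept explicit seeds; with a fixed
`SimConfig.seed` the entire truth set is bitwise reproducible. The
test suite and the acceptance script run at desk scale: populations of
~260–1,300 individuals, ~2k markers, 20-replicate recovery
experiments, 2,000+-test calibration batches — sizes chosen so a full
run completes on a single CPU in minutes while leaving every
statistical check well-powered.

## Interface choice

The package is a library: the importable API plus `examples/` scripts
are the interface. The analyses it implements are multi-step and
parameter-rich in a way that fits a notebook or script, not a shell
one-liner, so no command-line entry points are shipped; I/O helpers
(VCF via cyvcf2, dosage TSV, CSV) cover the interchange formats.

## Known limitations

* No genotype-call error model; platform differences reduce to marker
  sets and missing rates.
* Founders are simulated in linkage equilibrium; background LD in real
  panels is stronger at short range and weaker at long range than the
  family LD the pedigree induces.
* Family phasing requires both parents phased and genotyped;
  population imputation of parentless individuals is out of scope.
* Pedigree F assumes non-inbred founders; the simulator's truth shows
  the size of that bias but real pedigrees cannot.
* The dominance matrix follows the heterozygosity coding; orthogonal
  (natural-and-orthogonal) partitions would change variance-component
  interpretation, not predictions.
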
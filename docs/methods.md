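# Methods

This note documents the models behind each stage, the synthetic-data
generators that stand in for the study's real inputs, the numerical
choices, and what the tests do and do not establish about real data.

## Synthetic reference panels and LD

Genotypes are simulated from AR(1) latent Gaussians thresholded to
per-haplotype allele indicators; an individual's dosage is the sum of two
independent haplotypes. Thresholding attenuates correlation (a bivariate
normal at correlation ρ yields binary indicators correlated ≈ (2/π)·asin ρ
at MAF 0.5), so the latent step correlation is *calibrated* per block — by
bisection on the equal-threshold bivariate normal CDF, written with Owen's
T function — such that the **dosage** correlation between adjacent
variants equals the requested `within_block_corr`. MAF is drawn per block
(shared within a block), which keeps every target correlation attainable
after thresholding. Correlation decays approximately geometrically with
in-block distance (slightly slower than geometric, because the
thresholding attenuation is concave); variants in different blocks are
independent.

Passing an interval for `within_block_corr` draws the adjacent correlation
per block uniformly. This heterogeneity matters: LD score regression is a
regression *across* SNPs of χ² on ℓ, and with homogeneous blocks the true
spread of ℓ is so small that estimation noise in ℓ dominates and the slope
is attenuated (we measured ≈25% downward bias on h² with uniform 0.5
blocks). The study condition used throughout is blocks of 20 SNPs at
10-kb spacing with adjacent correlation uniform on (0, 0.98), giving ℓ
from ~1 to ~13 and a small fraction of r² > 0.9 pairs for the
fine-mapping candidate machinery.

Every generator is a pure function of its seed; per-stage child seeds are
derived as `SeedSequence([master, crc32(stage_name)])` and recorded in
output file headers.

## Planted architectures

`plant_truth` draws per-variant standardized causal effects and then
rescales them exactly so that (a) summed contributions equal `h2_total`
and (b) each annotation category's h² share equals
`enrichment × prop_snps` (the complement absorbs the remainder; requested
enrichments may not claim more than 100% of h²). The invariants "Σ
contributions = h²" and "realized enrichment = requested" therefore hold
to machine precision, and each replicate draws a fresh architecture so
recovery studies are unbiased. Cross-trait effects are drawn with the
planted genetic-correlation matrix.

Summary statistics are generated in "z-only" mode:
z = √N·R·β + √a·chol(R)·η blockwise, with R the panel's empirical block
correlation, so E[z z'] = a·R + N·R·diag(h²ⱼ)·R. Sample overlap between
traits enters the noise correlation as N_overlap·r_pheno/√(N_a·N_b)
(defaults: full overlap, phenotypic correlation equal to the planted r_g).

## LD score regression

`compute_ld_scores` uses the adjusted estimator r̂² − (1−r̂²)/(n−2) within
a 1-Mb window, clipping negative adjusted values at zero (keeps
ℓ_base ≥ 1 and scores interpretable; the clip adds ≲0.02 to ℓ at panel
size 1,500). `block_ld_scores` instead sums the squared *empirical* block
correlations — in the generative twin the panel R **is** the population
LD, so this is the exact regressor and avoids errors-in-variables
attenuation; it is what the recovery studies and analysis scripts use.
The adjusted path is for external data where the panel is a finite sample
of the LD in the association cohort.

Fits use the standard LDSC weights 1/(ℓ·2(Nℓh²/M + a)²) from an unweighted
first pass, shared between the univariate and stratified fitters (so a
base-only stratification reduces to the univariate fit exactly).
Uncertainty is by delete-one jackknife over 200 contiguous-SNP blocks.
Stratified fits regress χ² on all category scores; τ_c = coef_c/N;
prop_h2 follows from the τ model; the enrichment p-value is a jackknife
z-test on (prop_h2 − prop_snps). Collinear categories are dropped with a
warning, keeping the base. Genetic correlation divides the cross-trait
slope by the geometric mean of the univariate slopes; the free cross-trait
intercept absorbs sample overlap; the jackknife re-runs the whole
three-regression pipeline per deleted block. For identical inputs the
cross regression coincides with the univariate one, so rg = 1 exactly.

χ² winsorization at max(80, 0.001·N) — the convention of the tool the
design follows — is exposed as `chi2_cap`. The desk-scale recovery
studies disable it: with M = 10⁴ and N·h²/M = 1.5 per unit ℓ, χ² values
above 80 are genuine polygenic signal, and capping them biases h² and
enrichment downward (measured ≈5% on h², ≈8% on enrichment). On
biobank-scale data the cap guards against single outlier loci and should
stay on.

A caveat surfaced by the acceptance work: the univariate fit assumes
uniform per-SNP h². Under a strongly stratified architecture (2% of SNPs
at 9-fold), the univariate intercept acquires a panel-dependent offset of
up to ±0.3 depending on where the enriched blocks fall relative to
high-LD blocks. Whole-genome h²/intercept/r_g are therefore reported
under the uniform architecture, enrichment under the stratified one.

## Loci and candidates

Clumping is greedy in ascending p (ties break on genomic position); a
significant SNP is absorbed iff r² ≥ 0.6 with an earlier lead. Missing LD
raises — never silent independence; pairs beyond the 1-Mb window are 0 by
the window convention. Loci are unions of all panel variants (tested or
not) with r² > 0.6 to a lead, with blocks merged when ≤250 kb apart
(units interpreted as kb; exposed as a flag), numbered in genomic order.
Candidates are panel variants with r² > 0.9 to a lead, each recording its
best lead; untested candidates carry no p-value. All three operations are
verified against exhaustive brute-force oracles on random ≤100-SNP
instances.

## Gene-level tests

The gene statistic is the mean χ² of SNPs inside the gene body (closed
interval; no flanking window; the MHC-like exclusion list is an
argument). Under the null, member z-scores are MVN(0, R), so k·T is a
weighted sum of 1-df chi-squares with weights the eigenvalues of R. The
tail is evaluated by Gil-Pelaez/Imhof numeric inversion on a fixed grid:
the truncation point U is chosen from the integration-by-parts envelope
bound (4/q)/(U·ρ(U)) ≤ 10⁻¹⁰, the grid resolves 16 points per oscillation
period (capped at 4×10⁶ points, Monte-Carlo fallback at 10⁶ draws), and
the all-equal-eigenvalue case short-circuits to the exact scaled χ²_k —
which also makes a single-SNP gene return its SNP p exactly. Measured
accuracy is ≲0.5% relative against 4×10⁶-draw Monte Carlo across
eigenvalue shapes, and type-I error at α = 0.01 over 10⁴ correlated null
draws is 0.0097.

Gene-set and gene-property tests are OLS of the probit gene z on
membership (or a cell type's expression), one-sided for positive
coefficients, controlling log gene length, log SNP count, and LD density
(mean off-diagonal r² among member SNPs). The property test additionally
conditions on the per-gene across-type average (the row mean; a `center`
flag switches to the median), which annihilates signal whenever all cell
types share one profile. Quantile normalization maps each log(TPM+1)
column to the mean sorted profile with ties receiving interpolated
reference values at averaged ranks.

## Chromatin intervals

All intervals are 0-based half-open and strand-agnostic. Replicate
merging is intersect semantics (portions of rep1 overlapping rep2, ≥1 bp)
on union-merged inputs; blacklist overlap removes whole peaks rather than
trimming (common ATAC practice). Chain maps follow the UCSC format ('+'
strands only; the generator emits '+' chains); a peak spanning several
chains is projected through the best-scoring one and flagged. A peak is
accepted iff ≥50% of its bases fall in aligned blocks; the output spans
the projected bases on the target.

Permutation enrichment re-places each query interval, lengths preserved,
uniformly in *flattened* workspace coordinates (intervals may straddle
workspace segment joins — a ≤1-interval-length edge effect, negligible at
desk scale); the reference coverage is a piecewise-linear cumulative
function, so each permutation is two interpolations per interval. The
statistic is base-pair overlap (a `mode="count"` flag counts intervals
instead); fold = observed/mean(null);
p = (1 + #{null ≥ obs})/(n_perm + 1), never anti-conservative beyond the
1/(n+1) granularity. State enrichment is the ratio of query to workspace
base composition per state, with SE across chromosomes; states absent
from the workspace are flagged.

## Single-cell stage

Counts live in AnnData (cells × genes, `var['mito']`). QC removes cells
with <50 or >20,000 total UMIs (both strict) or mitochondrial fraction
>20%; the generator plants violators by construction well clear of the
boundaries, so "exactly the planted violators" is a meaningful check.
Normalization is library-size to 10,000 + log1p (the cited toolchain's
convention; the source only says "log normalized"). Variable genes use
the Seurat convention: binned mean in [0.0123, 3] and standardized LogVMR
dispersion ≥ 0.5 — the two bounds apply to the *mean* (x-cutoffs) and the
0.5 to dispersion, as in the original tool; a dispersion ceiling would
discard exactly the strongest markers. Clustering: optional covariate
regression (cell-cycle score = mean normalized expression of a
configurable gene list, mito fraction, total UMI), scaling, PCA to 10
components, SNN graph, and modularity community detection (Leiden
implementation; any correct modularity optimizer is acceptable) at
resolution 0.6, deterministic given the seed.

Markers are two-sided Wilcoxon rank-sums of in-cluster vs all other
cells: an exact tie-aware p by dynamic programming over the doubled
midrank multiset when min(group sizes) ≤ 8 (the null is symmetric about
n₁(n+1)/2 even with ties, since reversing order maps midranks to their
reflections), and the normal approximation with tie correction otherwise.
Bonferroni across genes within cluster. Specificity ranks clusters by
(p, |log fold change| descending, cluster label) — deterministic; genes
with maximum in-cluster detection below 5% are reported not-expressed.
The hair-cell meta-analysis fits log expression ~ group + age per
dataset, converts the one-sided t-p to a signed z, combines Z = Σz/√k
with equal weights over the datasets that measured the gene, and flags
genes at Benjamini-Hochberg FDR < 0.1.

The count generator emulates cell-type-structured negative-binomial UMIs
(var = μ + 0.3μ²), lognormal depth (mean 2,000 UMIs), a mitochondrial
gene subset at 5% of UMIs, and marker genes at planted fold-changes whose
baseline weight is pinned (0.5) so the fold — not a random lognormal draw
— sets their expression; without pinning, markers stochastically land
outside the variable-gene mean window. It does not model ambient RNA,
doublets, batch effects, or gene-length bias, so passing tests show the
pipeline recovers planted structure, not that it is robust to those
artifacts.

## Polygenic scores

Cohort QC applies, in order: individual missingness >10%, SNP missingness
>10%, MAF <5%, and the Hardy-Weinberg *exact* test at p < 10⁻⁶
(Wigginton-style recurrence over heterozygote counts; a vectorized
chi-square prefilter skips the exact computation when the asymptotic p is
nowhere near the threshold). Scoring harmonizes alleles against the
target (strand-ambiguous A/T and C/G SNPs dropped), optionally clumps in
the target panel (r² 0.1 within 250 kb, the scoring tool's convention),
mean-imputes missing dosages, and sums β·dosage over SNPs at each p
threshold (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1). Evaluation reports the
incremental R² of the score over covariates via nested OLS with the
F-test p; both incremental and marginal (no-covariate) use are supported
since the source leaves this ambiguous.

The target-cohort generator draws genotypes from the panel's latent
process and builds per-frequency thresholds as
25 + 10·(shared factor + noise_sd·ε_f), where the shared factor mixes the
standardized polygenic score built from `score_weights` (weight
√score_r2) with independent variation — so "planted score-explainable
variance" is exactly the R² an ideal PC1 regression recovers. With
noise_sd = 0.3 and three frequencies, PC1 carries ≈97% of the shared
factor, and the planted 5% is recovered to within a few tenths of a
percentage point on average. Audiometric realism (frequency-dependent
heritability, age structure) is not modeled.

## Problem sizes

Recovery studies use M = 10,000 SNPs, N = 50,000, panels of 1,500
individuals, 20 replicates for point-recovery checks and 100 for null
calibration; the single-cell stage uses 2,000 cells in 10 types; the PRS
stage 1,500 individuals × 4,000–10,000 SNPs. These sizes give
Monte-Carlo error comfortably below the tolerances being checked while
keeping the full suite in a few minutes on one core.

## Known limitations

- LD is blockwise by construction; there is no inter-block LD, no MAF-LD
  coupling, and no realistic allele-frequency spectrum (spec'd non-goals).
- The LDSC desk-scale regime (mean χ² ≈ 4–6) is far from biobank reality
  (≈1.1–1.3); conclusions about estimator behavior transfer qualitatively,
  not quantitatively.
- `map_intervals` handles '+' strand chains only.
- The permutation sampler does not forbid overlap among placed query
  intervals (matches the reference sampler's default closely at low
  query density).
- Single-cell mRNA age covariates, and the day-0/day-2 ambiguity of the
  source tissue, are not modeled; the meta-analysis age covariate is
  synthetic.
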
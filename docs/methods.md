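# Methods

## Scope and model of the data

`loykit` operates downstream of alignment and counting: its inputs are
per-cell chromosome-level count summaries (RNA transcript counts per
chromosome; ATAC fragment counts per chromosome and per retained 1 Mb
bin) together with per-cell metadata (donor, sex, age, cell type,
disease status). Cells below depth thresholds — fewer than 10,000 ATAC
fragments or 1,000 RNA transcripts; both must hold for multiome cells,
and the bounds are inclusive — are excluded before any LOY statistics
are computed, because low-depth cells cannot distinguish true chrY
absence from undersampling.

## Coverage normalization

For each cell and chromosome the normalized coverage is
`v = ln(1 + n_chrom / n_total)` (log1p of the count fraction; the
pseudocount is applied after normalization, identically for both
modalities). Cell types differ in chrY expression and accessibility
for reasons unrelated to LOY, so per (chromosome, modality) a
median-ratio correction `r_ct = median_global / median_celltype` is
computed and `v_corr = v · r_ct`. The medians are taken over male cells
passing QC by default (`male_only_medians=False` switches to all
cells); a zero cell-type median with a nonzero global median yields
factor 1 with a logged warning. The correction leaves each cell type's
median at the global pre-correction median exactly, since the median
commutes with positive scaling.

Corrected values are standardized to z-scores within each (donor,
chromosome, modality) stratum with the n−1 sample standard deviation.
Strata with one cell or zero spread get z = 0 and a degenerate flag;
cell type is deliberately not a scaling stratum (the median-ratio
correction already handles it). Donor-wise scaling makes thresholds
comparable across donors with different depth profiles.

## Trough genotyping

A Gaussian kernel density is estimated on the pooled male chrY
z-scores over a 512-point grid spanning [min − 3h, max + 3h]. The
bandwidth is the rule-of-thumb normal-reference rule
`h = 0.9 · min(sd, IQR/1.349) · n^(−1/5)`, chosen to mirror the
default of the R `density` estimator that popularized this style of
analysis; no per-dataset tuning is done. Modes are interior local
maxima that clear two floors: 1% of the peak height, and the height
that `min_mode_points` (default 5) isolated observations would produce
under the kernel (`5 · K(0)/(n·h)`). The second floor suppresses tail
ripples that a handful of outlying cells create in large unimodal
samples; both floors scale with the sample rather than any particular
cohort. The threshold is the density minimum between the two highest
modes, which makes it robust to minor ripples elsewhere. If fewer
than two modes survive, the status is `no_trough` and genotyping is
refused — the expected outcome on female or LOY-free input. Cells
strictly below the threshold are LOY; a cell exactly at the threshold
is called XY (conservative toward the majority genotype; a
measure-zero event).

## Joint two-modality mixture

Multiome cells have a chrY z-score in each modality. The joint
genotyper is a two-component Gaussian mixture on `(z_RNA, z_ATAC)`
with spherical covariances of component-specific volume
(`Σ_k = σ_k² I`) — the minimal shape that lets the tight LOY cluster
and the broad intact-Y cluster have different scales without learning
full covariances from few LOY cells. It is semi-supervised in the
strict sense: cells with zero raw chrY counts in both modalities are
fixed LOY, cells above the per-modality median z in either modality
are fixed XY (a cell matching both rules keeps the origin/LOY label
and is logged), and only the remaining cells' responsibilities are
updated by EM. Parameters initialize from the labeled cells' sample
statistics; convergence is a relative change in the total
(labeled + unlabeled) log-likelihood below 1e−8, and that objective is
non-decreasing by the EM argument. A component variance falling below
1e−8 aborts with an error naming the component, as does an absence of
labeled cells for either state. `labels_as_init_only=True` relaxes
the label fixing to initialization only.

## CNV burden

Autosomal 1 Mb bins (sex and mitochondrial chromosomes excluded;
blacklisted repeat-rich bins dropped up front) are corrected for GC
bias per cell: bins are grouped into GC deciles and counts in a
decile are rescaled by the cell's overall mean bin count over its
decile mean. The construction preserves the cell's total exactly and
removes monotone GC trends without fitting a curve. Each cell's
corrected counts are converted to fractions of its total and divided
by the per-bin population mean fraction over the analyzed cells (the
per-library analysis unit), making the ratio series depth-invariant.

Per chromosome, the ratio series is segmented by recursive binary
segmentation: a change point is accepted when it reduces the residual
sum of squares by more than `σ̂² · log n` (σ̂ estimated per cell from
the median absolute first difference, `σ̂ = MAD(Δr)/(0.6745·√2)`),
with a minimum segment length of 10 bins — stable at 1 Mb resolution.
Segments with mean ratio ≥ 1.2 are gains, ≤ 0.8 losses, else neutral;
per-cell burden is the fraction of retained bins in a non-neutral
state. This is a deliberately lean re-derivation of binned
single-cell CNV calling: the downstream association model consumes
only the burden proportion, which this reproduces on simulated truth
(whole-chromosome 1.5× spike-ins at per-bin mean ≥ 20 are recovered in
>90% of affected cells with <5% non-neutral bins elsewhere). The
thresholds and penalty are fixed design constants, not fitted.

## Association model

The LOY risk model is a logistic GLMM with a Gaussian random intercept
per donor. The marginal likelihood integrates the donor effect with a
Laplace approximation: for donor d,
`ℓ_d = log p(y_d | u*_d) − u*²/(2σ²) − ½ log(1 + σ² W_d)` where `u*` is
the per-donor posterior mode (found by a vectorized Newton iteration)
and `W_d = Σ p(1−p)` the conditional information. The outer
optimization is L-BFGS-B over (β, log σ) with log σ bounded in
[−8, 3]; at the lower bound the model is numerically an ordinary
logistic regression, which is how σ = 0 data behave (verified against
`statsmodels.Logit` to <1e−3 in the test suite). Design columns are
standardized internally for
conditioning and the coefficients and Wald covariance are mapped back;
the covariance is the inverse observed information (numeric Hessian),
restricted to the β block when σ sits on the boundary. Cell type is
treatment-coded against the proximal tubule ("PT") reference, so the
reference odds ratio is identically 1; complete separation in a
cell-type level raises an explicit error naming the level. Inference
is Wald (OR = exp β, CI = exp(β ± 1.96 SE)), matching how such models
are conventionally reported.

Marginal probabilities are `expit(xβ)` on a covariate grid with the
random effect at 0 (the population-median donor), with delta-method
bands on the linear predictor; population-averaged integration over u
is intentionally not the default. Donor-level summaries: Pearson
correlation of per-donor LOY proportion with age computed on donor
points (10-year age bins are provided for presentation only), and
two-group comparisons by exact two-sided Wilcoxon rank-sum on donor
proportions with mean ± sd per group.

Known limitation: with ~20 donors the maximum-likelihood estimate of
the random-intercept SD carries the usual downward finite-sample bias
of variance components (order σ/J; there is no REML analogue in ML
logistic GLMMs). The fixed effects and their CI coverage are
unaffected in our recovery tests; σ̂ should be read as an ML point
estimate, not an unbiased one.

## Digital PCR

Poisson partition statistics: if molecules disperse independently into
N wells at mean λ per well, the positive-well count is
Binomial(N, 1 − e^(−λ)), so `λ̂ = −ln(1 − k/N)`. The raw well-count
ratio `k_Y/k_X` (the assay's textual definition) is biased toward 1 at
moderate occupancy because positivity is nonlinear in λ; the
Poisson-corrected ratio `λ̂_Y/λ̂_X` is asymptotically unbiased below
saturation and is the default in simulation work — both are always
recorded. Guards: no chrX-positive wells is a reference failure; a
saturated plate cannot be Poisson-corrected. The LOY fraction is
`1 − chrY/chrX` clamped to [0, 1] (a ratio above 1 logs a warning),
which assumes the chrX concentration is constant. A male:female DNA
mixture with male mass fraction m carries 1 Y and 1 X per male
genome-equivalent and 2 X per female genome-equivalent, hence expected
ratio `m/(2 − m)`; the simulated mixing series uses λ_X = 0.5
(mid-dynamic-range occupancy) and 4 replicate plates per point,
matching a 2 technical × 2 batch replicate structure.

## Synthetic cohorts

The generator draws per-cell genotypes from
`logit P(LOY) = β₀ + β_ct + β_age·age + β_cnv·burden + β_ckd·CKD + u_donor`,
`u ~ N(0, σ²)`, and emits Poisson counts given each cell's expected
per-chromosome fractions. Defaults describe a kidney-cortex-like
cohort: 8 donors aged 40–80 alternating control/CKD, σ = 0.5, a
six-type cell mix led by proximal tubule with an injured PT_VCAM1
state at elevated LOY odds and podocytes strongly protected, age
effect 0.02 log-odds/yr, CKD effect 0.4, lognormal depths with
medians 3,000 (RNA) and 15,000 (ATAC), intact-Y chrY fractions of
0.005 (RNA) and 0.004 (ATAC) scaled by per-type accessibility, and
sporadic chr7 gains (2% of cells at fold 1.5). Ambient chrY
contamination in true-LOY cells defaults to 0 (0.02 in robustness
tests): real ambient rates are not well characterized, and the default
keeps the genotyping problem honest without making it impossible. The
toy genome is 22 autosomes with approximate real Mb lengths plus
chrX ≈ 155 Mb and chrY ≈ 57 Mb; non-Y expectation is distributed by
copy-number-weighted length (males carry one X), and optional XX cells
receive no structural chrY signal. The CNV burden entering the
generative logistic model is the true simulated burden, so CNV-caller
error cannot contaminate GLMM recovery tests.

What the generator does not emulate — and what passing tests therefore
do not demonstrate on real data: overdispersed counts (Poisson only;
a dispersion parameter is a natural config extension), doublets,
batch and ambient-RNA structure beyond the single chrY contamination
rate, read-level artifacts, partial-chromosome CNV, and LOX. Counts
are conditionally independent given depth and genotype, which makes
the genotyping problem cleaner than reality at matched depths.

## Problem sizes and numerics

Recovery checks run at sizes chosen to make Monte-Carlo noise small
relative to the asserted tolerances: genotyping on a 10,000-cell
multiome cohort (5 donors); GLMM recovery on 50 cohorts of 20 donors ×
100 cells; CNV spike-ins on 500 cells at per-bin mean ≥ 20; dPCR
precision on 100 replicate plates. Determinism: every stochastic
routine takes a seed (or `numpy` Generator) and cohort generation is
fully determined by `CohortConfig.seed`. Numerical floors and
tie-breaks are stated where they apply: GMM variance floor 1e−8, EM
relative tolerance 1e−8, trough ties to XY, correction factor 1 on
zero medians, z = 0 in degenerate strata, inner Newton tolerance
1e−12.
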
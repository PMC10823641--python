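# loykit

Mosaic loss of the Y chromosome (LOY) is the most common somatic
chromosomal alteration in aging men: a fraction of a man's cells simply
lack chrY. `loykit` detects and models LOY in single-cell kidney data —
single-nucleus multiome (joint RNA + ATAC), snATAC-seq and scRNA-seq —
and quantifies it orthogonally with microwell digital PCR. It is aimed
at analysts who have per-cell chromosome-level count summaries (not
reads) and want per-cell LOY genotypes, per-cell CNV burden, and
donor-level risk-factor models.

## What it computes

**Genotyping.** Per-cell chrY coverage is normalized
(`v = ln(1 + n_chrY / n_total)`), corrected across cell types by the
ratio of the global to the cell-type median (removing cell-type-specific
chrY accessibility/expression), and standardized within each
(donor, chromosome, modality) stratum. In a male cohort with LOY the
scaled chrY coverage `z` is bimodal; the trough of a Gaussian kernel
density estimate is the genotyping threshold (`z < t` ⇒ LOY). For
multiome data the two modalities are combined by a two-state
semi-supervised Gaussian mixture on `(z_RNA, z_ATAC)` with spherical,
component-specific covariances `Σ_k = σ_k² I`: cells at the origin (no
chrY coverage in either modality) are pre-labeled LOY, cells above the
median in either modality are pre-labeled XY, and EM classifies the
rest.

**CNV burden.** Autosomal 1 Mb bin counts are GC-corrected
(decile-stratum factors), compared as depth-normalized ratios to a
per-bin population mean, segmented per chromosome by least-squares
binary segmentation with a BIC-style penalty, and each segment is called
gain/neutral/loss by fold thresholds (1.2 / 0.8). Burden = proportion
of non-neutral bins per cell.

**Association.** A logistic generalized linear mixed model

    logit P(LOY_i) = x_i'β + u_d(i),    u_d ~ N(0, σ²)

with a random intercept per donor, fixed effects for cell type (vs the
proximal tubule), age, CNV burden and CKD, fitted by maximum likelihood
with a Laplace approximation of the per-donor integral. Reported as
odds ratios with Wald 95% CIs, plus marginal probability curves,
donor-level age correlation and group comparisons.

**Digital PCR.** A sample is partitioned into ~20,000 microwells; from
the chrY- and chrX-positive well counts the copy ratio is estimated
either raw (`k_Y / k_X`) or Poisson-corrected
(`λ = −ln(1 − k/N)`, ratio `λ_Y / λ_X`), and the LOY fraction is
`1 − chrY/chrX`. A male:female DNA mixture with male mass fraction `m`
has expected copy ratio `m / (2 − m)`.

All of it is exercised end-to-end on a synthetic cohort generator
(`loykit.simulate`) that draws per-cell genotypes from the same logistic
mixed model, emits Poisson chromosome/bin counts with donor-varying LOY
fractions, cell-type chrY accessibility offsets, depth variation and
sporadic whole-chromosome gains — with ground-truth labels for every
cell.

## Worked example

```python
import loykit as lk

cfg = lk.CohortConfig(n_donors=4, n_cells_per_donor=1500, seed=7)
cohort = lk.simulate_cohort(cfg, make_bin_matrix=False)

rna, atac = lk.filter_multiome(cohort.tables["RNA"], cohort.tables["ATAC"])
scaled, factors = lk.normalize_and_correct(atac)
chry = lk.chry_z(scaled)

clf = lk.estimate_density_threshold(chry["z"])
calls = lk.call_unimodal(chry, clf)
overall, per_donor = lk.loy_proportions(calls)
print(f"threshold z = {clf.threshold_:.3f}")
print(f"called LOY proportion = {overall:.3f}")

fit = lk.fit_glmm(cohort.truth.rename(columns={"true_genotype": "genotype"}),
                  covariates=["cell_type", "age"])
print(fit.table.round(3).to_string(index=False))
```

prints

```
threshold z = -1.586
called LOY proportion = 0.142
               term   beta    se    or  ci_low  ci_high     p
        (Intercept) -2.705 0.457 0.067   0.027    0.164 0.000
     cell_type[DCT] -0.350 0.119 0.704   0.558    0.889 0.003
    cell_type[ENDO] -0.952 0.173 0.386   0.275    0.542 0.000
    cell_type[PODO] -2.301 0.416 0.100   0.044    0.226 0.000
cell_type[PT_VCAM1]  0.216 0.120 1.242   0.981    1.571 0.071
     cell_type[TAL]  0.077 0.097 1.080   0.894    1.305 0.423
                age  0.017 0.007 1.017   1.002    1.032 0.023
```

The ATAC trough at z = −1.586 separates the LOY mode from the intact-Y
mode; the called LOY proportion (14.2%) matches the generator truth
(14.2%). The mixed model recovers the generative structure: podocytes
are strongly protected (OR 0.10), the injured PT_VCAM1 state trends
toward elevated odds, and LOY odds rise ~1.7% per year of donor age.

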
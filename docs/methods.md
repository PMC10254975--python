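# Methods

## Model and procedure

`methsets` analyses a paired methylome (CpG × sample beta values in
[0,1]) and transcriptome (gene × sample log2 expression) from the same
individuals, with a binary exposure and covariates.

**Per-feature linear model.** Each feature y (a CpG's beta values or a
gene's log2 expression) is modelled as `y = Xβ + ε`, `ε ~ N(0, σ²I)`,
with X containing an intercept, the 0/1 exposure, continuous covariates
(age, BMI, alcohol), sex, dummy-encoded socioeconomic status,
principal-component scores, and (for methylation) estimated cell-type
proportions with one type dropped. Beta values are modelled directly on
the [0,1] scale rather than as M-values; effect sizes are then mean
methylation differences, the scale on which results are reported. OLS
gives per-feature `(β̂_g, s_g, d)` with `d = n − rank(X)` shared across
complete features, and `SE_g = s_g√v`, `v = [(XᵀX)⁻¹]_jj`.

**Empirical-Bayes moderation.** Residual variances are modelled as
scaled inverse chi-square draws: `s²_g | σ²_g ~ σ²_g χ²_d/d`,
`1/σ²_g ~ χ²_{d₀}/(d₀s₀²)`. `(d₀, s₀²)` are estimated by the method of
moments on `z_g = log s²_g`: the mean and (bias-corrected) variance of
`e_g = z_g − ψ(d/2) + log(d/2)` are matched to `log s₀² + ψ(d₀/2) −
log(d₀/2)` and `ψ′(d₀/2)`; `ψ′` is inverted by Newton iteration
(tolerance 1e-8 on the relative step). When the observed spread of
log s² does not exceed the chi-square sampling spread, `d₀ = ∞` and all
variances collapse to `s₀²` (reported, not an error). Posterior
variances `s̃²_g = (d₀s₀² + d s²_g)/(d₀+d)` give moderated
`t̃_g = β̂_g/(s̃_g√v)` on `d₀+d` df (normal when `d₀ = ∞`), two-sided
p-values, and BH FDR. `d₀ = 0` reproduces the ordinary t-test exactly;
the implementation is cross-checked in the test suite against the R
limma implementation on a shared fixture.

**Genomic inflation.** p-values are mapped to 1-df chi-square quantiles;
λ is the ratio of their median to 0.4549364. λ is logged as a
calibration diagnostic only and never used to rescale p-values.

**Cell composition.** Houseman-type constrained projection: per sample,
`min‖P·w − β_panel‖²` s.t. `w ≥ 0`, solved by NNLS over the reference
profile matrix P (six leukocyte types), then renormalised to `Σw = 1`
(configurable). Panel CpGs are sorted before solving, so estimates are
invariant to panel row order. Granulocytes — the dominant type — are
dropped when the proportions enter a design matrix, avoiding the
sum-to-one collinearity.

**Gene sets.** CpGs with EWAS `p < α/n_tests` (strict inequality;
`n_tests` defaults to the number of probes analysed) are split by
coefficient sign into hypo-/hypermethylated. For each of the 8 region
categories — the 7 array labels plus Promoter = TSS1500 ∪ TSS200 ∪
5′UTR ∪ 1stExon — and each direction, the set contains every gene with
at least one contributing (probe, gene, region) link. Links are stored
gene-specifically, so a probe in the body of gene A and the TSS200 of
gene B contributes each gene under its own label. Multi-gene probes
contribute to all linked genes; intergenic probes to none. Genes at DGE
FDR < 0.05 in the same data (plus any user-supplied list) are removed,
because the question is precisely whether the set test sees what
single-gene analysis misses. A gene may appear in both directions of a
region via different probes; this is allowed and reported. Empty sets
are retained with size 0.

**Rotation gene set test.** For the expression matrix and the DGE
design, each gene's sample vector is projected onto the orthonormal
basis from the QR factorisation of X with the tested column last: one
effect coordinate `z₁` (sign-aligned with the coefficient) and `d`
residual coordinates. The EB prior `(d₀, s₀²)` is estimated once from
all genes and held fixed. Each rotation draws a single uniform random
unit vector `r` in the (d+1)-space, shared by every gene: `z₁* = rᵀz`,
`s*² = (‖z‖² − z₁*²)/d`, moderated `t̃*` as above. Sharing `r` across
genes preserves the inter-gene correlation structure within a rotation —
the property that distinguishes rotation from gene permutation — and the
test stays calibrated under exchangeable inter-gene correlation (checked
at ρ = 0.3). Set statistics: up = mean(t̃), down = −mean(t̃), mixed =
mean(|t̃|) by default ("msq", mean t̃², is available; the mean statistic
is the conventional default of this family of tests and is validated
here by calibration and power simulations rather than by equivalence to
any external implementation). `p = (b+1)/(nrot+1)` where b counts
rotations with statistic ≥ observed; the attainable minimum is
1/(nrot+1). One-sided up/down and the mixed p use the same rotation
draws. Across sets, BH is applied within each hypothesis column
separately (FDR.up, FDR.down, FDR.mixed); per-set rotation streams are
seeded from the master seed plus a CRC32 of the sorted membership, so
identical sets always yield identical p-values.

**ORA.** `p = P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, with the universe
restricted to measured genes (platform-coverage correction); up- and
downregulated lists are tested separately; BH across terms.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any real
cohort. Defaults mirror a large adult whole-blood study: n = 1114 with
13.5% exposed, beta-scale exposure effects |Δβ| around 0.006–0.05 (the
magnitude range of genome-wide-significant smoking CpG coefficients),
logit-scale residual SD 0.12 (≈ 0.02–0.03 on the beta scale at
mid-range methylation, matching typical EPIC residual spread), log2
expression SD 0.5, and coordinated expression shifts of +0.15 log2 —
deliberately below single-gene detectability at these sample sizes so
that only the set-level test can see them.

Methylation is built on the logit scale: probe baseline ~ N(0, 1.2²)
(logit-normal marginals, mid-range baselines for affected probes so the
planted beta-scale difference fits in (0,1)); covariate effects on a
random 30% of features with N(0, scale²) coefficients over standardized
covariate encodings; an optional cell-composition layer replacing panel
probes' baseline with the sample's Dirichlet-mixed reference profile
(with a granulocyte tilt in exposed samples, so deconvolution has a real
confound to remove — off by default); the exposure effect as the logit
shift `logit(p₀+Δβ) − logit(p₀)`, so at vanishing noise the realized
group difference equals Δβ exactly; then N(0, 0.12²) noise and the
inverse logit, which bounds beta in (0,1) without truncation. The truth
ledger records every (probe, gene, region, direction, Δβ) link and every
expression-shifted gene; expression shifts go to genes whose own
(region, direction) link matches a configured cell, i.e. exactly the
genes a perfect EWAS would place in that set. Probe picks prefer unused
genes so planted cells stay distinct.

Annotation: each gene gets one probe per region label plus Poisson
extras; 20% of probes are intergenic; 5% of gene-linked probes link two
genes. Autosomes only — matching the analysed feature space after QC.

What the generator does **not** emulate: raw intensities and detection
p-values (QC operates on supplied matrices), probe-type chemistry
differences, CpG-island spatial correlation along the genome, batch
structure beyond generic covariate confounding, and count-based
(RNA-seq) expression noise. Passing tests therefore demonstrate the
statistical machinery — calibration, power for coordinated shifts,
de-confounding — under the model's assumptions, not performance on any
particular array's artefacts.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen so each check
exercises the relevant asymptotics: end-to-end runs use 200 samples
(30% exposed), 240 genes, ~2,400 probes, effects in all 16 (region,
direction) cells and coordinated upregulation only for the
hypomethylated-body genes; 3 PC scores in each design (30/10 remain the
`PipelineConfig` defaults, proportionate to full-scale matrices, but at
a few thousand features the exposure itself becomes a top variance
direction and more PCs would begin to absorb it); rotation calibration
uses 500 replicates at nrot = 199 (rejection at α = 0.05 is exactly
achievable since 0.05·(nrot+1) is an integer); EB prior recovery uses
20,000 features at d = 10.

Other numerical choices: QR (complete mode) for the rotation basis with
the sign fixed to the tested coefficient; PCA sign fixed by making each
component's largest-|loading| positive; BH via the standard step-up
(statsmodels); rotation statistics computed in rotation blocks capped at
~4·10⁷ elements to bound memory; probes with zero residual variance are
flagged rather than dropped; features with missing values are dropped
from fits and listed.

QC defaults: probe removed when detection p > 0.01 in more than 1% of
samples (the permissive published variant of this rule — removal only
when failing in *more than 99%* of samples — is available via
`probe_fail_sample_fraction=0.99`); sample aggregate rule is the mean of
detection p-values < 0.01, with "sum" as a config option for pipelines
that specify it; exclusion reasons applied in fixed order (detection →
sex chromosome → cross-reactive → SNP) so reports are disjoint and
deterministic.

## Known limitations

- Self-contained testing only; no competitive (camera-style) test, so a
  global expression shift in exposed samples would make many sets
  significant at once (λ and the null-calibration tests guard the
  per-set error rate, not set specificity under global shifts).
- Single tested coefficient; no contrast systems, interactions or mixed
  models.
- Gene identity is the annotation's symbol string; no alias resolution
  or trans (distal) CpG–gene mapping.
- The ORA stage does not propagate the GO graph or reduce term
  redundancy.
- QC starts from beta/detection-p matrices; platform-specific intensity
  preprocessing (background/dye-bias correction, quantile
  normalisation) is out of scope.
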
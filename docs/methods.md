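# Methods

## The construction

The meta-memory ratio treats awareness of cognitive decline as a signed
discrepancy between what a participant reports and what their tests show,
*relative to their cohort*. Three modelling commitments follow:

1. **Demographic residualization per score, per cohort.** Age, gender and
   education are associated with both test performance and complaint, and
   the two cohorts a study compares will generally differ on them. Each
   score is therefore fit as the dependent variable of a GLM on
   {intercept, age, gender, education} strictly within its cohort, and only
   the residual enters the statistic. The family is *declared* in the score
   registry, never inferred from the data: the analyst knows whether a score
   is a bounded count (binomial, with `max_value − min_value` trials and a
   logit link), a near-zero-inflated error tally (binarized as
   `count > threshold`, default threshold 0, then Bernoulli), or effectively
   continuous (Gaussian). Automatic family inference would silently change
   the estimand between datasets.

2. **Residual type.** Non-Gaussian GLMs admit several residual definitions.
   The default is the *response* residual (observed − fitted mean): it is
   defined identically across families, and the z-scoring that follows
   absorbs any scale differences, which is the only property the composite
   needs. Deviance and Pearson residuals are available by configuration and
   the choice is recorded in the per-fit metadata, so an audit can see
   exactly what was computed.

3. **Orientation before averaging.** Summing an intrusion-count residual
   with a complaint residual without sign alignment would invert the
   statistic's meaning for that score. Direction is therefore a mandatory
   field of every score declaration; `higher_worse` objective columns are
   flipped after z-scoring. The composite is an unweighted mean — the point
   of the statistic is transportability, and weights estimated in one cohort
   would not transport.

The MMR is the **sum** O + S of the two composites, not a difference:
orientation puts performance and complaint on scales where the sum carries
the intended semantics (a well-aware decliner has low O and low S, summing
to ≈ 0 only when they match in magnitude). The MMR itself is *not*
re-standardized; its within-cohort mean is 0 by construction, but its spread
(sd ≈ 1.1–1.2 under the default generator) is data, not convention.

Zero-variance covariates are dropped from a residualization design (they are
aliased with the intercept and carry no demographic signal) and recorded in
the fit metadata; rank errors are reserved for genuine collinearity between
non-constant covariates, and the error names an aliased column. Sample
standard deviations use the n−1 denominator throughout; any consistent
choice cancels downstream, but it must be fixed for reproducibility.

## Biomarker harmonization

Amyloid SUVr is divided by a cohort-specific positivity threshold (defaults
0.79 and 1.11 for the INSIGHT-PreAD and ADNI processing dialects; any other
cohort must declare its own), mapping every cohort's positivity boundary to
1. This is a deliberate simplicity/accuracy trade-off: a common-scale
conversion such as Centiloid is more accurate but requires calibration data
the consuming study may not have. The FDG meta-ROI (mean over posterior
cingulate, inferior parietal lobule, precuneus, inferior temporal gyrus —
configurable) has no established cutoff and is z-scored within cohort with
the same n−1 convention.

## Inference

The MMR model is ordinary least squares on
`age + gender + education + cohort + fdg + av45 + av45² + av45:fdg +
av45:cohort + fdg:cohort`. The squared amyloid term is a **raw** square —
no centering or orthogonal polynomials — so that the reported linear and
squared coefficients define a parabola directly on the normalized-SUVr axis
and the vertex −β_lin/(2·β_quad) is readable against the positivity
boundary at 1. Gender, education and cohort enter as 0/1 indicators with
declared reference levels (female, higher education, INSIGHT-PreAD when
present).

Term tests are type-II likelihood-ratio tests: each term is dropped from
the model containing all other terms, with marginality enforced — a main
effect is tested in models that exclude its interactions, and requesting a
comparison that drops a main effect while retaining its interaction raises
a contract-violation error rather than silently fitting a meaningless pair.
The linear and squared amyloid terms are tested jointly as one 2-df effect
(their split is not separately interpretable on the raw-polynomial basis).
The LRT statistic is 2·Δloglik against a χ² reference; at the sample sizes
this package targets (hundreds of rows) it agrees with the exact F test to
well within reporting precision, and a test asserts that agreement.
Cohen's f² uses the same nested pair: (R²_full − R²_reduced)/(1 − R²_full),
clamped at 0 against floating-point noise (a nested pair cannot have
negative f²). P-values are reported raw, with no multiple-testing
correction.

Two vertex variants are reported: from the full interaction model and from
a main-effects-only refit. They answer slightly different questions (the
full-model coefficients are conditional on interaction terms); neither is
privileged.

Influence diagnostics expose the hat diagonal and Cook's distance per
observation (leverage numerically 1 is reported as infinite distance, not
an exception); the package deliberately makes no automatic outlier
exclusion — screening thresholds are the analyst's call. Normality and
heteroskedasticity checking is likewise left to the analyst (residual and
fitted arrays are exportable); no plotting contract is provided.

Cohort-description statistics are Welch's t from summary statistics
(mean, sd, n per group; Welch–Satterthwaite df) and Pearson's χ² on 2×2
count tables with Yates continuity correction **on by default** — the
correction-on convention is the one that matches standard cohort-table
reporting for small 2×2 cells.

## The synthetic cohort generator

The generator emulates the structure the pipeline assumes, with defaults
fixed at the study conditions the package targets: two cohorts of 158 and
290 participants; ages 71.97 ± 5.79 vs 76.02 ± 3.5; 60.1% vs 63.1% female;
99.4% vs 67.6% higher education; raw SUVr 1.01 ± 0.16 (threshold 1.11) vs
0.86 ± 0.17 (threshold 0.79), drawn truncated-positive, with an optional
two-component mixture for amyloid-positive subpopulations; FDG meta-ROI
1.30/1.25 ± 0.12 (the FDG moments are arbitrary up to the intra-cohort
z-step, which removes them).

The latent model is
`A = β_lin·x + β_quad·x² + β_fdg·z_fdg + ε` with defaults β_lin = 9,
β_quad = −4 (vertex 1.125, just past the positivity boundary), β_fdg = 0.5,
ε ~ N(0, 1). A shared cognitive level u ~ N(0, 0.8) splits A symmetrically:
latent memory M = u + A/2, latent complaint C = −u + A/2, so M + C = A
exactly and the two latent channels have equal variance ≈ 1 under the
defaults (0.8 was chosen for that reason: var(A)/4 + 0.8² ≈ 1). Observed
scores add declared demographic effects and pass through the family link;
note that dividing a raw SUVr mean of 1.01 by threshold 1.11 versus 0.86 by
0.79 makes the *second* cohort more amyloid-positive on the normalized
scale — a direct consequence of parameterizing both cohorts' raw moments
from printed summary tables whose raw-vs-normalized status is ambiguous for
one cohort; the generator states its inputs and leaves them as declared.

Two presets share this truth and differ only in the score battery:

* `default_config()` — a realistic mixed-family battery (a 0–48 binomial
  recall count, a Gaussian figure-recall score, a logistic intrusion
  indicator, a Gaussian complaint scale), used for construction-invariant
  checks. Nonlinear links attenuate the latent signal, so raw-coefficient
  recovery is *not* expected here.
* `recovery_config()` — one linear objective and one linear subjective
  score with unit loadings and small (sd 0.15) measurement noise. Because
  both links are linear and the latent channels have ≈ unit variance, the
  pipeline MMR is an almost unbiased copy of A and the fitted amyloid
  coefficients estimate the generating β directly. All calibration checks
  (type-I error, CI coverage, sign recovery, power) use this preset.

What the generator does **not** emulate: real covariance between memory
subtests beyond the shared latent, item-level questionnaire structure,
missingness mechanisms (tables are complete by construction; the ingest
filter is tested separately), longitudinal structure, or realistic
correlations between demographics and biomarkers. Passing tests therefore
certify the pipeline's algebra and its statistical calibration under the
declared generative model, not distributional fidelity to any real cohort.

## Problem sizes and numerical choices

Stochastic test batteries use pinned seeds and these sizes, chosen to give
stable verdicts at interactive runtimes: type-I error of the combined 2-df
amyloid LRT — 1000 replicates at n = 448 (accepted band 3–7% at nominal
5%); CI coverage of β_quad — 500 replicates at n = 448 (band 93–97%); sign
recovery — 200 replicates; power monotonicity — 60–100 replicates per grid
point over three effect sizes (quadratic amplitude scaled with the vertex
held fixed) and three sample sizes; p-value uniformity under the null —
120 replicates at 4× the default n with a Kolmogorov–Smirnov check.

The per-cohort z-step makes each score column's total variance exactly 1,
which mildly *stabilizes* the fitted coefficients relative to their nominal
standard errors; measured CI coverage under the recovery preset is
therefore slightly above 95% (≈ 96–97%), inside the accepted band.

Numerical conventions: linear-family residuals via least squares
(`numpy.linalg.lstsq`); binomial/logistic fits via IRLS (statsmodels GLM,
200-iteration cap, non-convergence and separation raised as estimation
errors, a constant outcome raised as degenerate); rank checks via SVD-based
matrix rank with aliased-column identification; LRT statistics floored at 0
against round-off; a constant vector is detected by zero range, not just
zero computed sd. Determinism: one `numpy.random.Generator` seeded per
simulation drives all draws in a fixed order, so identical (config, seed)
pairs produce byte-identical CSV output.
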
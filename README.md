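# mmratio

Awareness of cognitive decline (ACD) — the degree to which a person's
self-reported cognitive complaints match their measured cognitive
performance — is a promising early marker in preclinical Alzheimer's
disease: complaints in excess of measured decline (subjective cognitive
decline, SCD) and measured decline in excess of complaint (anosognosia) both
carry information about underlying pathology. Comparing ACD across studies
is hard because cohorts use different memory tests, different complaint
questionnaires, and different imaging pipelines.

`mmratio` implements the **meta-memory ratio (MMR)**, a cohort-independent
discrepancy statistic, together with the biomarker harmonization and
regression machinery needed to relate it to amyloid and FDG PET. It is a
library for epidemiologists and neuropsychologists working with cohort
tables (CSV) of per-participant scores and precomputed imaging scalars.

## The statistic

Within each cohort, independently:

1. every registered score *s* (objective memory tests and subjective
   complaint measures) is entered as the dependent variable of a GLM
   `s ~ age + gender + education` under its declared family (linear,
   binomial, or logistic), and the residuals are extracted — scores net of
   demographic effects;
2. residuals are z-scored (mean 0, sd 1, denominator *n*−1) to make scales
   comparable, and oriented so that higher always means *better performance*
   for objective scores (error and intrusion counts are sign-flipped) and
   *more complaint* for subjective ones;
3. the oriented objective columns are averaged into a composite *O*, the
   subjective columns into *S*;
4. **MMR = O + S**.

By construction the MMR has mean 0 within each cohort; MMR ≫ 0 is SCD-like
(complaint without measured decline), MMR ≪ 0 is low awareness (decline
without complaint), MMR ≈ 0 is accurate awareness.

Biomarkers are harmonized by dividing each cohort's amyloid SUVr by its own
positivity threshold (defaults: 0.79 for the INSIGHT-PreAD dialect, 1.11 for
ADNI), so normalized SUVr > 1 means amyloid-positive everywhere, and by
z-scoring the FDG meta-ROI mean within cohort. The headline inference is the
OLS fit

```
mmr ~ age + gender + education + cohort + fdg + av45 + av45² +
      av45:fdg + av45:cohort + fdg:cohort
```

with type-II likelihood-ratio tests (the linear and squared amyloid terms
jointly as a 2-df effect), Cohen's f² effect sizes, the parabola vertex
−β_lin/(2·β_quad) on the normalized-SUVr axis, and Cook's distance / hat
values for influence screening. A two-cohort synthetic data generator with a
known quadratic amyloid–awareness truth supports testing and parameter
recovery.

## Worked example

```python
import mmratio as mm

sim = mm.simulate_cohorts(mm.default_config(), seed=42)   # 158 + 290 rows
tables = list(sim.tables.values())
results = [mm.cohort_mmr(t) for t in tables]              # the MMR pipeline
panels = [mm.harmonize(t) for t in tables]                # SUVr/threshold, FDG z
data = mm.build_model_frame(tables, results, panels)
report = mm.fit_mmr_model(data)
```

Running `python examples/03_fit_quadratic_model.py` (which does exactly
this) prints, among other rows:

```
av45            8.041  2.150
av45_sq        -3.488  0.988
...
av45           19.4005  2.0  0.0001
...
full-model vertex: normalized SUVr 1.153 (maximum)
```

Read: the fitted awareness curve in this synthetic dataset rises with
amyloid load (linear coefficient 8.04 ± 2.15), turns over (squared
coefficient −3.49 ± 0.99), and peaks at a normalized SUVr of 1.15 — just
past the positivity boundary at 1 — with the joint 2-df amyloid test at
p ≈ 10⁻⁴. The generating truth was a parabola with coefficients 9 and −4.

Summary-level cohort comparisons need no participant data
(`examples/04_cohort_comparisons.py`):

```
age:       t = -8.03, df = 221.0, p = 5.78e-14
gender:    chi2 = 0.27, p = 0.604
education: chi2 = 59.94, p = 9.79e-15
```

The `examples/` directory has one short script per capability; the
`mmratio` command exposes the same pipeline as `simulate`, `compute`
(cohort CSVs → per-participant MMR and harmonized biomarkers) and `fit`
(→ model report JSON) subcommands.

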
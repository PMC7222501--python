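"""Recover known generative coefficients through the full pipeline.

The recovery scenario uses a single linear objective score and a single
linear complaint score, so the pipeline MMR is an (almost) unbiased copy of
the latent awareness signal and the fitted amyloid coefficients can be
compared directly with the generating truth.
"""

import mmratio as mm

cfg = mm.recovery_config()
truth = cfg.truth
sim = mm.simulate_cohorts(cfg, seed=1)

tables = list(sim.tables.values())
results = [mm.cohort_mmr(t) for t in tables]
panels = [mm.harmonize(t) for t in tables]
data = mm.build_model_frame(tables, results, panels)
report = mm.fit_mmr_model(data, lrt=False, diagnostics=False)

print(f"{'term':<10}{'truth':>8}{'estimate':>10}{'se':>8}")
for term, value in [("av45", truth.b_lin), ("av45_sq", truth.b_quad), ("fdg", truth.b_fdg)]:
    est = report.coefficients.loc[term, "estimate"]
    se = report.coefficients.loc[term, "se"]
    print(f"{term:<10}{value:>8.2f}{est:>10.2f}{se:>8.2f}")

lrt = mm.lrt_type2(data, "av45")
print(f"\ncombined amyloid (linear+squared) LRT: stat {lrt.statistic:.1f}, "
      f"df {lrt.df}, p {lrt.pvalue:.2e}")
print(
    "\nEstimates land within sampling error of the generating coefficients;\n"
    "the joint 2-df test detects the quadratic amyloid effect decisively."
)
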
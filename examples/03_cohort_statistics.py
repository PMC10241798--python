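"""Simulate a paired pre/post-chemotherapy cohort and run the statistics layer.

A 40-patient phantom cohort is generated with one planted association
(pre-treatment COV vs recurrence, target Spearman rho = +0.34), features are
extracted identically for both timepoints, and the report shows which
features the paired Wilcoxon test flags as changed by therapy and how the
planted correlation is recovered and banded.
"""

import petromics as pm

cspec = pm.CohortSpec(
    n_patients=40,
    seed=11,
    planted_effects=(("pre_cov", "recurrence", 0.34),),
)
bundle = pm.generate_cohort(cspec)
features = pm.extract_bundle(bundle)
report = pm.run_cohort_analysis(features, bundle.clinical)

print("Planted ground truth:")
print(bundle.planted.to_string(index=False))
print()

paired = report.paired_change
sig = paired[paired.p_value < 0.05]
print("Features changed by therapy (paired Wilcoxon, p < 0.05):")
for _, row in sig.iterrows():
    print(f"  {row.feature:15} Z = {row.z:+.2f} ({row.direction}), p = {row.p_value:.2g}")
print("(Z > 0 means the feature decreased after chemotherapy.)")
print()

corr = report.correlations
cell = corr[(corr.feature == "pre_cov") & (corr.covariate == "recurrence")].iloc[0]
print(
    f"Recovered pre_cov x recurrence: rho = {cell.rho:+.2f} "
    f"({cell.band}), p = {cell.p_value:.3g}  [target was +0.34]"
)
print("(n = 40 is deliberately small; sampling noise on rho is ~0.15 here,")
print(" the calibration itself is verified at n = 200 in the test suite)")
print()
print("Cohort composition (counts and rounded percentages):")
summary = pm.cohort_summary(bundle.clinical)
print(summary[summary.variable.isin(["n", "recurrence", "response"])].to_string(index=False))
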
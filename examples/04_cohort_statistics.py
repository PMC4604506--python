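"""Simulate a phantom cohort end to end and run the outcome statistics.

Eight phantom subjects with varying resections and deficits are processed
through the full pipeline; Engel outcomes are drawn from a null logistic
model, so none of the volumetric predictors should separate the outcome
groups beyond chance.
"""

from perifocal import simulate_cohort

cohort, report = simulate_cohort(n_subjects=8, seed=2)

print(f"processed {len(cohort)} subjects; outcome split: "
      f"{(cohort.engel_class == 'I').sum()} Engel I vs "
      f"{(cohort.engel_class != 'I').sum()} Engel II-IV\n")

cols = ["voi", "tracer", "outcome", "n", "pre_mean_mm3", "resected_mean_mm3",
        "post_mean_mm3", "p_value"]
print("pre/post abnormality volumes by subgroup (paired t on the reduction):")
print(report.pre_post[cols].round(1).to_string(index=False))

print("\nunivariate logistic models (odds ratio per unit, C-statistic):")
print(report.logistic[["voi", "variable", "odds_ratio", "p_value", "c_statistic"]]
      .round(4).to_string(index=False))

print(f"\n{report.n_tests} tests at alpha 0.05, no multiplicity correction;")
print("under the null outcome model, C-statistics hover near 0.5 and small-n")
print("p-values are noisy - exactly what a negative volumetric study looks like.")
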
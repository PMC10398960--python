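"""Outlier cleansing, mixed model, EMMs and Tukey contrasts.

Simulates the full three-cohort design (12 + 11 + 4 animals), applies
the ±2SD per-stratum outlier rule, fits the animal-random-intercept
mixed model, and reports estimated marginal means and the key aging
contrast in the dentate granule cell layer.
"""

from hippomech import fit_mixed_model, remove_outliers, tukey_contrasts
from hippomech.synthgen import CohortDesign, simulate_cohort

design = CohortDesign(points_per_region=100, seed=3)
data = simulate_cohort(design)
cleaned, report = remove_outliers(data.points)
frac = report["n_removed"].sum() / len(data.points)
print(f"outlier rule removed {report['n_removed'].sum()} of "
      f"{len(data.points)} points ({frac:.1%})")

model = fit_mixed_model(cleaned)
emm = model.emm.set_index(["analysis_group", "cohort"])
print(f"\nbetween-animal SD: {model.random_intercept_var ** 0.5:.1f} Pa")
print("\nestimated marginal means (Pa), CA1 pyramidal and DG granule:")
for group in ("CA1_PYR", "DG_GCL"):
    for cohort in ("3mo-WT", "18mo-WT", "17mo-APP"):
        row = emm.loc[(group, cohort)]
        print(f"  {group:8s} {cohort:9s} {row.emm:6.0f} ± {row.se:.0f}")

contrasts = tukey_contrasts(model, mvt_seed=3)
dg = contrasts[
    (contrasts.group_1 == "DG_GCL")
    & (contrasts.cohort_1 == "18mo-WT")
    & (contrasts.cohort_2 == "3mo-WT")
].iloc[0]
print(f"\nDG granule, aged vs young WT: +{dg.estimate:.0f} Pa "
      f"(t = {dg.t:.1f}, adjusted p = {dg.p_adjusted:.2g})")
# The generator is calibrated to a 131 Pa stiffening of the dentate
# granule layer with healthy aging; the contrast recovers it and the
# Tukey-adjusted p-value flags it as highly significant.
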
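"""Cohort statistics on a synthetic three-group study.

Generates a cohort (23 controls, 10 patients with leading positive
symptoms, 21 with leading negative symptoms) with tissue MPF drawn from
the published group distributions, then runs the statistical battery:
MANCOVA with age covariate, Tukey HSD, effect sizes, and clinical
correlations.
"""

from mpfmap import cohort_stats, generate_cohort

cohort = generate_cohort(seed=1)
report = cohort_stats(cohort)

m3 = report.mancova["three_group"]
print(f"MANCOVA group factor: Wilks lambda {m3['group']['wilks_lambda']:.3f}, "
      f"F({m3['group']['df1']},{m3['group']['df2']:.0f}) = "
      f"{m3['group']['F']:.2f}, p = {m3['group']['p']:.2e}")
print(f"age covariate: lambda {m3['age']['wilks_lambda']:.3f}, "
      f"p = {m3['age']['p']:.3f}")

print("\nTukey HSD adjusted p-values (WM MPF):")
for pair, p in report.pairwise["wm_mpf"].items():
    print(f"  {pair}: p = {p:.4f}")

print("\neffect sizes vs controls:")
for key in ("sz_negative_vs_control:gm_mpf", "sz_negative_vs_control:wm_mpf"):
    e = report.effects[key]
    print(f"  {key}: d = {e['cohens_d']:.2f}, "
          f"decrease = {e['percent_decrease']:.1f}%")

dur = report.correlations["patients:disease_duration:wm_mpf"]
print(f"\nWM MPF vs disease duration (patients): r = {dur['r']:.2f} "
      f"(p = {dur['p']:.3f}), age-adjusted partial r = {dur['partial_r']:.2f} "
      f"(p = {dur['partial_p']:.3f})")
print("-> the synthetic cohort reproduces the study's qualitative findings: "
      "a strong multivariate group effect and a negative duration-WM "
      "association surviving age adjustment.")
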
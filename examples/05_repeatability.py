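"""Scan-rescan repeatability of tissue MPF means.

Simulates two measurements of the rescan subgroup (8 controls) with
independent measurement noise and summarizes agreement by Bland-Altman
bias and limits of agreement, a paired t-test, and the within-subject
coefficient of variation per tissue class.
"""

from mpfmap import generate_cohort, repeatability
from mpfmap.synthetic import simulate_measured_means

cohort = generate_cohort(seed=1)
rescan = cohort[cohort.rescan].reset_index(drop=True)
scan1, scan2 = simulate_measured_means(rescan, measurement_sd=0.08, seed=2)

report = repeatability(scan1, scan2)
print(f"scan-rescan pairs: {report.n_pairs}")
for tissue, m in report.per_tissue.items():
    print(f"{tissue}: bias {m['bias']:+.3f} pp, "
          f"LoA [{m['loa_low']:+.3f}, {m['loa_high']:+.3f}] pp, "
          f"paired-t p = {m['paired_t_p']:.2f}, CoV = {m['cov_percent']:.2f}%")
print("-> bias is indistinguishable from zero and the within-subject CoV "
      "tracks the measurement noise relative to the tissue mean "
      "(about 100 * sigma / mean).")
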
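"""Segment an MPF map into tissue classes and estimate myelin density.

Thresholds the map at MPF > 1%, fits the prior-initialized four-class EM
mixture (WM / GM / mixed WM-GM / CSF partial volume), extracts per-class
mean MPF, and converts the analysis classes to myelin density via the
histological calibration MPF = 0.21 x MD + 3.9.
"""

import warnings

from mpfmap import (
    PhantomSpec,
    make_phantom,
    mpf_to_myelin_density,
    protocol_preset,
    reconstruct_map,
    segment_map,
    simulate_acquisition,
    tissue_means,
)

protocols = protocol_preset()
tissues = {
    "WM": {"f": 0.1304, "r1": 1.5, "pd": 0.7},
    "GM": {"f": 0.0644, "r1": 0.9, "pd": 0.85},
}
phantom = make_phantom(PhantomSpec(), tissues, rng_seed=3)
images = simulate_acquisition(phantom, protocols, 0.01, rng_seed=4)
mpf_map = reconstruct_map(images, brain_mask=phantom.brain_mask)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    class_masks, seg, n_excluded = segment_map(mpf_map)
    means = tissue_means(mpf_map, class_masks)

print(f"voxels excluded by the 1% MPF threshold: {n_excluded}")
status = "converged" if seg.converged else "stopped"
print(f"EM {status} after {seg.n_iter} iterations; "
      f"class means {[float(round(m, 2)) for m in seg.means]} %")
for name in ("WM", "GM", "PVWGM"):
    mpf = means[name]
    md = mpf_to_myelin_density(mpf)
    print(f"{name}: mean MPF {mpf:.2f}% -> myelin density {md:.1f}%")
pvcsf = means["PVCSF_excluded"]
if pvcsf == pvcsf:
    print(f"(PVCSF is computed but excluded from analysis: {pvcsf:.2f}%)")
else:
    print("(PVCSF class empty on this phantom)")
print("-> mean MPF separates tissues cleanly; the calibration turns it "
      "into a histology-scale myelin density estimate.")
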
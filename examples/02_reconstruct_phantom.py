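"""Reconstruct an MPF map from a simulated three-sequence acquisition.

Builds a digital brain phantom with known ground truth, simulates the
MTw/T1w/PDw spoiled-GRE triplet with 1% noise, and reconstructs the MPF
map by the single-point synthetic-reference method (VFA fit of R1/PD,
computed no-saturation reference, voxel-wise inversion).
"""

import numpy as np

from mpfmap import PhantomSpec, make_phantom, protocol_preset, reconstruct_map, simulate_acquisition

protocols = protocol_preset()
tissues = {
    "WM": {"f": 0.1304, "r1": 1.5, "pd": 0.7},
    "GM": {"f": 0.0644, "r1": 0.9, "pd": 0.85},
}
phantom = make_phantom(PhantomSpec(), tissues, rng_seed=1)
images = simulate_acquisition(phantom, protocols,
                              noise_sigma_fraction=0.01, rng_seed=2)

mpf_map = reconstruct_map(images, brain_mask=phantom.brain_mask)
print(f"brain voxels: {mpf_map.log['n_brain_voxels']}, "
      f"invalid after inversion: {mpf_map.log['n_invalid']} "
      f"({100 * mpf_map.log['invalid_fraction']:.2f}%)")

valid = mpf_map.validity_mask
err = mpf_map.mpf_percent[valid] - 100.0 * phantom.mpf[valid]
print(f"per-voxel error: median |err| {np.median(np.abs(err)):.3f} pp, "
      f"95th percentile {np.percentile(np.abs(err), 95):.3f} pp")
for name in ("WM", "GM"):
    region = phantom.region_masks[name] & valid
    rec = mpf_map.mpf_percent[region].mean()
    tru = 100.0 * phantom.mpf[region].mean()
    print(f"{name}: region mean {rec:.3f}% vs truth {tru:.3f}% "
          f"(bias {rec - tru:+.4f} pp)")
print("-> 1% image noise leaves region-mean MPF accurate to a few "
      "hundredths of a percentage point.")
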
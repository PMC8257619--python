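"""In-memory composition of the phantom cohort pipeline.

Convenience wrappers that run simulate -> reconstruct -> segment ->
tissue means for a whole synthetic cohort without touching disk, and
score the recovery against the phantom ground truth.  The CLI offers the
same stages file-to-file; this module exists for validation studies and
scripted analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import TwoPoolConstraints
from .reconstruct import reconstruct_map
from .segment import segment_map, tissue_means
from .synthetic import CohortSpec, PhantomSpec, generate_cohort, simulate_subject_images

__all__ = ["process_subject", "phantom_cohort_recovery"]


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / denom


def process_subject(row, protocols, phantom_spec: PhantomSpec,
                    noise_sigma_fraction: float, seed: int,
                    constraints: TwoPoolConstraints | None = None) -> dict:
    """Simulate, reconstruct and segment one subject; score vs truth.

    Returns recovered and ground-truth per-class mean MPF (percent) plus
    WM/GM Dice overlap of the EM masks against the phantom regions,
    restricted to the analyzed (thresholded) voxels.
    """
    images, phantom = simulate_subject_images(
        row, protocols, phantom_spec,
        noise_sigma_fraction=noise_sigma_fraction, seed=seed,
        constraints=constraints)
    mpf_map = reconstruct_map(images, constraints, phantom.brain_mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        class_masks, seg, _ = segment_map(mpf_map)
        means = tissue_means(mpf_map, class_masks)
    analyzed = np.zeros_like(phantom.brain_mask)
    for m in class_masks.values():
        analyzed |= m
    truth_pct = 100.0 * phantom.mpf
    out = {
        "subject_id": row["subject_id"],
        "group": row["group"],
        "invalid_fraction": mpf_map.log["invalid_fraction"],
    }
    for name in ("WM", "GM", "PVWGM"):
        out[f"recovered_{name.lower()}"] = means[name]
        out[f"truth_{name.lower()}"] = float(
            truth_pct[phantom.region_masks[name]].mean())
    for name in ("WM", "GM"):
        out[f"dice_{name.lower()}"] = _dice(
            class_masks[name] & analyzed,
            phantom.region_masks[name] & analyzed)
    return out


def phantom_cohort_recovery(spec: CohortSpec | None = None,
                            phantom_spec: PhantomSpec | None = None,
                            protocols=None, seed: int = 0,
                            constraints: TwoPoolConstraints | None = None) -> pd.DataFrame:
    """Run the full image-level pipeline over a synthetic cohort.

    Generates the cohort table, builds one phantom per subject from the
    subject's true tissue MPF, simulates the three-sequence acquisition
    with the spec's noise, reconstructs and segments each map, and
    returns a per-subject table of recovered vs ground-truth class means
    and Dice overlap.
    """
    from .protocols import protocol_preset

    if spec is None:
        spec = CohortSpec()
    if phantom_spec is None:
        phantom_spec = PhantomSpec()
    if protocols is None:
        protocols = protocol_preset()
    cohort = generate_cohort(spec, seed=seed)
    child = np.random.SeedSequence(seed).generate_state(len(cohort)) % (2 ** 31)
    rows = [process_subject(row, protocols, phantom_spec,
                            spec.noise_sigma_fraction, int(child[i]),
                            constraints)
            for i, row in cohort.iterrows()]
    return pd.DataFrame(rows)
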
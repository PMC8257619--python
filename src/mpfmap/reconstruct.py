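"""Single-point synthetic-reference MPF reconstruction.

Pipeline per brain-masked voxel:

1. :func:`vfa_fit` — two-point variable-flip-angle (VFA) solution of the
   Ernst equation on the PD-/T1-weighted pair, yielding ``R1`` and proton
   density ``PD``.
2. :func:`synthetic_reference` — a computed no-saturation reference signal
   at the MT-weighted sequence's TR and flip angle.
3. ``MTw / reference`` — the normalized MT signal, insensitive to PD and
   (with shared TE) to T2* weighting.
4. :func:`solve_mpf` — 1-D inversion of the two-pool steady-state model
   for the macromolecular proton fraction ``f``.

No B0/B1 field-inhomogeneity correction is applied anywhere in this
module; source volumes are assumed co-registered on a common grid.  All
steps are vectorized and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import (
    AcquisitionProtocol,
    TwoPoolConstraints,
    spoiled_gre_signal,
    two_pool_signal,
)

__all__ = [
    "SourceImageSet",
    "MPFMap",
    "vfa_fit",
    "synthetic_reference",
    "solve_mpf",
    "reconstruct_map",
]

#: Upper end of the MPF search bracket, as a fraction (35%): covers
#: physiological values with a wide margin.
F_MAX = 0.35

#: Absolute tolerance of the MPF root, as a fraction; well below
#: measurement noise.
F_TOL = 1e-5

#: Normalized signals in (model-max, this] are clamped to f = 0 instead of
#: invalidated: noise can push the measured ratio slightly above the
#: model's no-MT ceiling.
RATIO_CEIL = 1.05


@dataclass
class SourceImageSet:
    """The MTw/T1w/PDw volume triplet on a common grid.

    ``protocols`` maps ``{"mtw", "t1w", "pdw"}`` to their acquisition
    protocols; the MTw protocol must carry the MT pulse, the other two
    must not.
    """

    mtw: np.ndarray
    t1w: np.ndarray
    pdw: np.ndarray
    protocols: Mapping[str, AcquisitionProtocol]
    voxel_size: tuple[float, float, float] = (1.25, 1.25, 1.25)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.mtw.shape == self.t1w.shape == self.pdw.shape):
            raise ValueError("MTw/T1w/PDw volumes must share one grid")
        for key in ("mtw", "t1w", "pdw"):
            if key not in self.protocols:
                raise ValueError(f"protocols must include {key!r}")
        if self.protocols["mtw"].mt_pulse is None:
            raise ValueError("MTw protocol must include an MT pulse")
        if any(self.protocols[k].mt_pulse is not None for k in ("t1w", "pdw")):
            raise ValueError("T1w/PDw protocols must not include an MT pulse")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mtw.shape


@dataclass
class MPFMap:
    """Reconstructed MPF volume in percent units with its masks.

    ``validity_mask`` marks voxels where the inversion succeeded; it is a
    subset of ``brain_mask``.  Outside the validity mask ``mpf_percent``
    is zero.
    """

    mpf_percent: np.ndarray
    brain_mask: np.ndarray
    validity_mask: np.ndarray
    log: dict = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = (1.25, 1.25, 1.25)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.brain_mask = self.brain_mask.astype(bool)
        self.validity_mask = self.validity_mask.astype(bool)
        if self.validity_mask.shape != self.mpf_percent.shape:
            raise ValueError("masks must match the map grid")
        if np.any(self.validity_mask & ~self.brain_mask):
            raise ValueError("validity mask must be a subset of the brain mask")


def vfa_fit(pdw_signal, t1w_signal, pdw_protocol: AcquisitionProtocol,
            t1w_protocol: AcquisitionProtocol):
    """Two-point VFA fit of R1 and PD from the Ernst equation.

    Uses the linearization ``S/sin(a) = E * (S/tan(a)) + PD (1 - E)`` over
    the two flip angles (shared TR), so the slope between the two points
    gives ``E = exp(-TR R1)`` and the intercept gives PD.  Returns
    ``(r1, pd, valid)``; voxels with non-positive signals or a slope
    outside (0, 1) are marked invalid and carry NaN.
    """
    if abs(pdw_protocol.repetition_time - t1w_protocol.repetition_time) > 1e-12:
        raise ValueError("VFA pair must share TR")
    a1 = np.radians(pdw_protocol.excitation_flip_angle)
    a2 = np.radians(t1w_protocol.excitation_flip_angle)
    if abs(a1 - a2) < 1e-12:
        raise ValueError("VFA pair must use distinct flip angles")
    tr = pdw_protocol.repetition_time

    s1 = np.asarray(pdw_signal, dtype=float)
    s2 = np.asarray(t1w_signal, dtype=float)
    s1, s2 = np.broadcast_arrays(s1, s2)
    valid = (s1 > 0) & (s2 > 0) & np.isfinite(s1) & np.isfinite(s2)

    with np.errstate(divide="ignore", invalid="ignore"):
        y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
        y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)
        e = (y1 - y2) / (x1 - x2)
        pd = (y1 - e * x1) / (1.0 - e)
        r1 = -np.log(e) / tr
    valid &= np.isfinite(e) & (e > 0) & (e < 1) & np.isfinite(pd) & (pd > 0)
    r1 = np.where(valid, r1, np.nan)
    pd = np.where(valid, pd, np.nan)
    if r1.ndim == 0:
        return float(r1), float(pd), bool(valid)
    return r1, pd, valid


def synthetic_reference(r1, pd, mtw_protocol: AcquisitionProtocol):
    """Computed no-saturation reference signal for normalization.

    The Ernst signal at the MT-weighted sequence's TR and flip angle,
    evaluated from the VFA-fitted ``R1``/``PD`` — i.e. the signal the MTw
    scan would have produced with the saturation pulse off and no
    magnetization-transfer effect.
    """
    return spoiled_gre_signal(pd, r1, mtw_protocol.repetition_time,
                              mtw_protocol.excitation_flip_angle)


def _model_ratio(f, r1, protocol: AcquisitionProtocol,
                 constraints: TwoPoolConstraints, ernst):
    return two_pool_signal(f, r1, protocol, constraints, pd=1.0) / ernst


def solve_mpf(normalized_signal, r1, protocol: AcquisitionProtocol,
              constraints: TwoPoolConstraints | None = None,
              f_max: float = F_MAX, tol: float = F_TOL, max_iter: int = 100):
    """Invert the normalized MT signal for the MPF fraction.

    Finds the root in ``[0, f_max]`` of
    ``two_pool_signal(f) / ernst_reference - normalized_signal`` by
    vectorized bisection; the model ratio is strictly decreasing in ``f``,
    so the root is unique when bracketed.  Returns ``(f, valid)``.

    Voxels whose normalized signal exceeds the model's f = 0 ceiling but
    stays at or below ``RATIO_CEIL`` are clamped to ``f = 0`` (noise above
    the attainable range); signals above the ceiling or below the model
    value at ``f_max`` are invalid.
    """
    if constraints is None:
        constraints = TwoPoolConstraints()
    if protocol.mt_pulse is None:
        raise ValueError("solve_mpf requires a protocol with an MT pulse")
    y = np.asarray(normalized_signal, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    scalar = y.ndim == 0 and r1.ndim == 0
    y, r1 = np.broadcast_arrays(np.atleast_1d(y), np.atleast_1d(r1))
    y = y.astype(float)
    r1 = r1.astype(float)

    valid = np.isfinite(y) & np.isfinite(r1) & (r1 > 0) & (y > 0)
    r1_safe = np.where(valid, r1, 1.0)
    ernst = spoiled_gre_signal(1.0, r1_safe, protocol.repetition_time,
                               protocol.excitation_flip_angle)
    ratio_lo = _model_ratio(np.zeros_like(r1_safe), r1_safe, protocol,
                            constraints, ernst)
    ratio_hi = _model_ratio(np.full_like(r1_safe, f_max), r1_safe, protocol,
                            constraints, ernst)
    clamp_zero = valid & (y > ratio_lo) & (y <= RATIO_CEIL)
    valid &= (y <= RATIO_CEIL) & (y >= ratio_hi)

    lo = np.zeros_like(y)
    hi = np.full_like(y, f_max)
    # bisection halves the bracket; run until the bracket is below tol
    n_iter = min(max_iter, int(np.ceil(np.log2(f_max / tol))) + 1)
    active = valid & ~clamp_zero
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        rmid = _model_ratio(mid, r1_safe, protocol, constraints, ernst)
        go_up = rmid > y        # model ratio decreasing: root above mid
        lo = np.where(active & go_up, mid, lo)
        hi = np.where(active & ~go_up, mid, hi)
    f = 0.5 * (lo + hi)
    f = np.where(clamp_zero, 0.0, f)
    f = np.where(valid, f, np.nan)
    if scalar:
        return float(f[0]), bool(valid[0])
    return f, valid


def reconstruct_map(images: SourceImageSet,
                    constraints: TwoPoolConstraints | None = None,
                    brain_mask: np.ndarray | None = None) -> MPFMap:
    """Reconstruct an MPF map (percent units) from a source image set.

    Per masked voxel: VFA fit of (R1, PD), synthetic-reference
    normalization of the MTw signal, and single-point inversion for MPF.
    Voxels where any step fails are excluded from the validity mask; the
    reconstruction log records their counts.  Deterministic: identical
    inputs give bit-identical maps.
    """
    if constraints is None:
        constraints = TwoPoolConstraints()
    if brain_mask is None:
        brain_mask = np.ones(images.shape, dtype=bool)
    brain_mask = np.asarray(brain_mask).astype(bool)
    if brain_mask.shape != images.shape:
        raise ValueError("brain mask must match the image grid")

    mtw = images.mtw[brain_mask]
    t1w = images.t1w[brain_mask]
    pdw = images.pdw[brain_mask]

    r1, pd, valid_fit = vfa_fit(pdw, t1w, images.protocols["pdw"],
                                images.protocols["t1w"])
    ref = synthetic_reference(r1, pd, images.protocols["mtw"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mtw / ref
    ratio = np.where(valid_fit & (ref > 0), ratio, np.nan)

    f, valid_inv = solve_mpf(ratio, r1, images.protocols["mtw"], constraints)
    valid = valid_fit & valid_inv

    mpf_percent = np.zeros(images.shape, dtype=float)
    validity = np.zeros(images.shape, dtype=bool)
    vals = np.where(valid, 100.0 * f, 0.0)
    mpf_percent[brain_mask] = vals
    validity[brain_mask] = valid

    n_mask = int(brain_mask.sum())
    n_valid = int(valid.sum())
    log = {
        "n_brain_voxels": n_mask,
        "n_valid": n_valid,
        "n_invalid": n_mask - n_valid,
        "invalid_fraction": (n_mask - n_valid) / n_mask if n_mask else 0.0,
        "n_invalid_vfa": int((~valid_fit).sum()),
        "constraints": {
            "cross_relaxation_rate": constraints.cross_relaxation_rate,
            "t2_bound": constraints.t2_bound,
            "r1t2_free": constraints.r1t2_free,
            "bound_lineshape": constraints.bound_lineshape,
        },
    }
    return MPFMap(mpf_percent=mpf_percent, brain_mask=brain_mask,
                  validity_mask=validity, log=log,
                  voxel_size=images.voxel_size, affine=images.affine)
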
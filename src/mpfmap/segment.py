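"""Prior-initialized tissue segmentation of MPF maps.

An MPF map separates brain tissues by value alone: white matter (WM)
around 13%, gray matter (GM) around 6%, mixed WM/GM partial-volume voxels
(PVWGM) in between, and CSF partial-volume voxels (PVCSF) near 1%.  This
module fits a four-component 1-D Gaussian mixture by EM, with component
means initialized at those tissue priors, assigns voxels by maximum
posterior, and extracts per-class mean MPF.  PVCSF is computed but flagged
as excluded from downstream analysis; voxels at or below the 1% MPF
threshold are dropped before fitting.

The mixture-on-values approach deliberately replaces atlas- or
image-space-prior segmenters: the downstream statistics operate on means
over large tissue masks, for which a transparent intensity mixture with
the same initialization is sufficient and fully reproducible.  An optional
iterated-conditional-modes (ICM) pass adds 6-neighborhood spatial
smoothing; it is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .reconstruct import MPFMap

__all__ = [
    "CLASS_NAMES",
    "INIT_MEANS",
    "MPF_THRESHOLD",
    "SegmentationResult",
    "apply_mpf_threshold",
    "segment_em",
    "segment_map",
    "tissue_means",
]

#: Tissue classes in canonical order.
CLASS_NAMES = ("WM", "GM", "PVWGM", "PVCSF")

#: Initial component means in percent MPF: the tissue priors for WM, GM,
#: PVWGM and PVCSF respectively.
INIT_MEANS = (13.0, 6.0, 9.0, 1.0)

#: Voxels must exceed this MPF (percent) to enter segmentation; removes
#: residual CSF.  Strict inequality: voxels at exactly 1% are excluded.
MPF_THRESHOLD = 1.0

_VAR_FLOOR = 1e-6
_WEIGHT_COLLAPSE = 1e-4
_DUPLICATE_SEP = 1.0   # percent MPF; prior class centers are >= 2 pp apart


@dataclass
class SegmentationResult:
    """Four-class segmentation of the analyzed voxels.

    ``labels`` holds per-voxel class indices into :data:`CLASS_NAMES` for
    the 1-D value vector that was segmented; ``means``/``variances``/
    ``weights`` are the fitted mixture parameters after label matching.
    ``collapsed`` flags components that degenerated during EM (e.g. when
    the data contain fewer than four populations).
    """

    labels: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    collapsed: np.ndarray
    log_likelihood_path: np.ndarray = field(repr=False, default=None)

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == k))
                for k, name in enumerate(CLASS_NAMES)}


def apply_mpf_threshold(mpf_map: MPFMap, threshold: float = MPF_THRESHOLD):
    """Select analyzed voxels: valid and with MPF strictly above threshold.

    Returns ``(voxel_mask, n_excluded)`` where ``voxel_mask`` is a boolean
    volume and ``n_excluded`` counts valid voxels removed by the
    threshold.  Raises if nothing survives.
    """
    base = mpf_map.validity_mask
    keep = base & (mpf_map.mpf_percent > threshold)
    n_excluded = int(base.sum() - keep.sum())
    if not keep.any():
        raise ValueError("no voxels above the MPF threshold; nothing to segment")
    return keep, n_excluded


def _log_gauss(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def segment_em(values, init_means=INIT_MEANS, max_iter: int = 200,
               tol: float = 1e-6) -> SegmentationResult:
    """Fit a four-component 1-D Gaussian mixture to MPF values by EM.

    Components start at the ``init_means`` tissue priors with equal
    weights and equal variances (sample variance / 4).  EM runs until the
    log-likelihood gain drops below ``tol`` or ``max_iter`` iterations.
    A component whose variance collapses is re-seeded at its initial mean
    with a floor variance and flagged; components that end with
    negligible weight are flagged as collapsed as well.  After
    convergence, components are matched to the tissue classes by nearest
    initial mean (one-to-one assignment), guarding against label
    switching.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < len(init_means) or np.unique(x).size < len(init_means):
        raise ValueError("need at least 4 distinct values to fit 4 components")
    k = len(init_means)
    init_means = np.asarray(init_means, dtype=float)
    means = init_means.copy()
    var0 = max(float(np.var(x)) / k, _VAR_FLOOR)
    variances = np.full(k, var0)
    weights = np.full(k, 1.0 / k)
    collapsed = np.zeros(k, dtype=bool)

    ll_old = -np.inf
    ll_path = []
    converged = False
    n_iter = 0
    log_resp = None
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_p = (np.log(weights)[:, None]
                 + _log_gauss(x[None, :], means[:, None], variances[:, None]))
        log_norm = logsumexp(log_p, axis=0)
        log_resp = log_p - log_norm
        ll = float(np.sum(log_norm))
        ll_path.append(ll)
        if ll - ll_old < tol and n_iter > 1:
            converged = True
            break
        ll_old = ll
        # M-step
        resp = np.exp(log_resp)
        nk = resp.sum(axis=1)
        safe_nk = np.maximum(nk, 1e-300)
        weights = nk / x.size
        means = resp @ x / safe_nk
        variances = resp @ (x * x) / safe_nk - means ** 2
        # collapse handling: an effectively empty component is re-seeded at
        # its prior; a point-mass component merely has its variance floored
        bad = (nk < 1e-8) | ~np.isfinite(means) | ~np.isfinite(variances)
        if bad.any():
            for j in np.flatnonzero(bad):
                if not collapsed[j]:
                    warnings.warn(
                        f"mixture component {j} (init mean {init_means[j]:g}) "
                        "collapsed; re-seeded at its prior", RuntimeWarning)
                collapsed[j] = True
            means[bad] = init_means[bad]
            variances[bad] = var0
        variances = np.maximum(variances, _VAR_FLOOR)
        weights = np.maximum(weights, 1e-300)
        weights /= weights.sum()
    if not converged:
        warnings.warn("EM did not converge; returning best iterate",
                      RuntimeWarning)
    collapsed |= weights < _WEIGHT_COLLAPSE
    # components that merged onto the same mode (fewer populations than
    # components) are degenerate: flag the lighter of each close pair
    for i in range(k):
        for j in range(k):
            if i != j and abs(means[i] - means[j]) < _DUPLICATE_SEP:
                collapsed[i if weights[i] <= weights[j] else j] = True

    # match components to tissue classes by nearest init mean, one-to-one,
    # greedily from the closest pair; healthy components are matched before
    # collapsed ones so a spurious duplicate cannot steal an anchored class
    cost = np.abs(means[:, None] - init_means[None, :])
    order = np.empty(k, dtype=int)          # order[class] = component
    free_class = set(range(k))
    for comp_pool in (set(np.flatnonzero(~collapsed)),
                      set(np.flatnonzero(collapsed))):
        while comp_pool and free_class:
            i, j = min(((i, j) for i in comp_pool for j in free_class),
                       key=lambda ij: cost[ij])
            order[j] = i
            comp_pool.remove(i)
            free_class.remove(j)
    means = means[order]
    variances = variances[order]
    weights = weights[order]
    collapsed = collapsed[order]

    comp_labels = np.argmax(log_resp, axis=0)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)           # component -> class
    labels = relabel[comp_labels]

    return SegmentationResult(
        labels=labels, means=means, variances=variances, weights=weights,
        log_likelihood=ll_path[-1], n_iter=n_iter, converged=converged,
        collapsed=collapsed, log_likelihood_path=np.asarray(ll_path))


def _icm_pass(labels_vol, analyzed, values_vol, seg: SegmentationResult,
              beta: float, n_sweeps: int = 5):
    """Iterated conditional modes on the 6-neighborhood Potts prior."""
    k = len(CLASS_NAMES)
    lab = labels_vol.copy()
    inside = analyzed
    for _ in range(n_sweeps):
        # count like-labeled neighbors per candidate class
        energy = np.zeros((k,) + lab.shape)
        for c in range(k):
            energy[c] = -_log_gauss(values_vol, seg.means[c],
                                    seg.variances[c]) - np.log(seg.weights[c])
            same = np.zeros(lab.shape)
            for axis in range(lab.ndim):
                for shift in (1, -1):
                    sh = np.roll(lab == c, shift, axis=axis)
                    shm = np.roll(inside, shift, axis=axis)
                    same += (sh & shm)
            energy[c] -= beta * same
        new = np.argmin(energy, axis=0)
        new = np.where(inside, new, lab)
        if np.array_equal(new, lab):
            break
        lab = new
    return lab


def segment_map(mpf_map: MPFMap, threshold: float = MPF_THRESHOLD,
                init_means=INIT_MEANS, beta: float = 0.0):
    """Threshold and segment an MPF map; return masks and the EM result.

    Returns ``(class_masks, seg, n_excluded)`` where ``class_masks`` maps
    tissue names to boolean volumes that are pairwise disjoint and
    together cover exactly the analyzed voxels.  ``beta > 0`` enables the
    ICM spatial-regularization pass (off by default: the downstream
    statistics use means over large masks, where smoothing is
    second-order).
    """
    analyzed, n_excluded = apply_mpf_threshold(mpf_map, threshold)
    values = mpf_map.mpf_percent[analyzed]
    seg = segment_em(values, init_means=init_means)

    labels_vol = np.full(mpf_map.mpf_percent.shape, -1, dtype=int)
    labels_vol[analyzed] = seg.labels
    if beta > 0:
        labels_vol = _icm_pass(labels_vol, analyzed, mpf_map.mpf_percent,
                               seg, beta)
        seg.labels = labels_vol[analyzed]

    class_masks = {name: (labels_vol == k) & analyzed
                   for k, name in enumerate(CLASS_NAMES)}
    return class_masks, seg, n_excluded


def tissue_means(mpf_map: MPFMap, class_masks: dict[str, np.ndarray]):
    """Mean MPF (percent) per tissue class.

    Returns a dict with WM, GM and PVWGM means plus the PVCSF mean under
    the key ``"PVCSF_excluded"`` — it is computed for completeness but is
    not part of the analysis set.  Empty classes yield NaN with a warning.
    """
    out: dict[str, float] = {}
    for name in CLASS_NAMES:
        mask = class_masks[name]
        if not mask.any():
            warnings.warn(f"empty tissue class {name}", RuntimeWarning)
            value = float("nan")
        else:
            value = float(mpf_map.mpf_percent[mask].mean())
        key = name if name != "PVCSF" else "PVCSF_excluded"
        out[key] = value
    return out
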
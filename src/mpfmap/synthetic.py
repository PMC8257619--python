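"""Synthetic phantoms and cohorts for the MPF pipeline.

Real scans for this kind of study are rarely shareable, so validation
runs on synthetic data with known ground truth at two levels:

* **Digital phantoms** — a nested-ellipsoid "brain" (CSF core, WM core,
  a mixed WM/GM boundary shell, GM shell, CSF rim) with per-voxel
  ground-truth MPF, R1 and proton density, pushed through the forward
  two-pool signal model to produce the MTw/T1w/PDw source triplet with
  optional Gaussian or Rician noise.
* **Cohorts** — subject tables (three groups: healthy controls and
  patients with leading positive or negative symptoms) whose covariates
  and per-tissue MPF distributions follow the published group moments of
  a 1.5 T schizophrenia study, including the negative coupling between
  disease duration and white-matter MPF, and a scan-rescan subgroup for
  repeatability analysis.

Everything is seeded and deterministic: identical spec + seed gives
bit-identical outputs, noise included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TwoPoolConstraints, spoiled_gre_signal, two_pool_signal
from .reconstruct import SourceImageSet

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "make_phantom",
    "simulate_acquisition",
    "generate_cohort",
    "simulate_subject_images",
    "simulate_measured_means",
    "TISSUE_MPF_TABLE",
    "COVARIATE_TABLE",
]

# Group-level tissue MPF moments (percent): {group: {tissue: (mean, sd)}}.
TISSUE_MPF_TABLE = {
    "control": {"gm_mpf": (6.44, 0.24), "pvwgm_mpf": (9.22, 0.40),
                "wm_mpf": (13.04, 0.56)},
    "sz_positive": {"gm_mpf": (6.21, 0.35), "pvwgm_mpf": (9.07, 0.43),
                    "wm_mpf": (13.02, 0.56)},
    "sz_negative": {"gm_mpf": (6.07, 0.24), "pvwgm_mpf": (8.79, 0.37),
                    "wm_mpf": (12.45, 0.58)},
}

# Covariate moments per group: (mean, sd); None where not applicable.
COVARIATE_TABLE = {
    "control": {
        "age": (38.58, 9.55), "male_fraction": 0.38,
    },
    "sz_positive": {
        "age": (30.33, 4.42), "male_fraction": 0.56,
        "onset_age": (20.56, 4.33), "disease_duration": (9.11, 3.58),
        "cpz_equivalent": (443.3, 412.5),
        "panss_positive": (21.25, 6.1), "panss_negative": (18.50, 5.5),
        "panss_general": (42.75, 6.4), "panss_total": (82.51, 15.5),
    },
    "sz_negative": {
        "age": (42.17, 8.17), "male_fraction": 0.48,
        "onset_age": (23.83, 4.44), "disease_duration": (18.04, 6.36),
        "cpz_equivalent": (215.9, 212.4),
        "panss_positive": (17.71, 5.3), "panss_negative": (28.21, 3.8),
        "panss_general": (51.78, 9.1), "panss_total": (97.71, 19.2),
    },
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue-parameter layout of the digital phantom.

    The brain is a nested set of concentric ellipsoids parameterized by
    the normalized elliptical radius rho: a small CSF core, a WM core, a
    thin mixed WM/GM shell (per-voxel mixing weight uniform in (0, 1)),
    a GM shell, and a CSF rim, inside a brain mask at rho <= 1.

    R1 (1/s) and proton density defaults are typical 1.5 T magnitudes
    (WM 1.5, GM 0.9, CSF 0.25 1/s; PD 0.7 / 0.85 / 1.0); they shape
    realism only — the analysis operates on MPF.  The default 48-voxel
    cube keeps full-cohort simulations fast; any grid size is accepted.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 1.25
    # normalized-radius band edges: csf core | WM | PVWGM | GM | csf rim
    rho_edges: tuple[float, float, float, float] = (0.18, 0.58, 0.68, 0.88)
    semi_axes: tuple[float, float, float] = (0.95, 0.88, 0.82)
    r1: dict = field(default_factory=lambda: {"WM": 1.5, "GM": 0.9, "CSF": 0.25})
    pd: dict = field(default_factory=lambda: {"WM": 0.7, "GM": 0.85, "CSF": 1.0})
    csf_mpf: float = 0.002


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition, covariate moments, and noise settings.

    Defaults reproduce the study conditions: 23 controls, 10 patients
    with leading positive symptoms, 21 with leading negative symptoms;
    covariates and tissue MPF drawn from the published group moments; a
    target correlation of -0.51 between disease duration and WM MPF
    within each patient subgroup; 8 control subjects flagged for a rescan.
    """

    n_control: int = 23
    n_positive: int = 10
    n_negative: int = 21
    duration_wm_correlation: float = -0.51
    n_rescan_controls: int = 8
    noise_sigma_fraction: float = 0.01   # of mean brain PDw intensity
    noise_model: str = "gaussian"        # or "rician"
    tissue_mpf: dict = field(default_factory=lambda: TISSUE_MPF_TABLE)
    covariates: dict = field(default_factory=lambda: COVARIATE_TABLE)

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_positive, self.n_negative) < 0:
            raise ValueError("group sizes must be non-negative")
        if not abs(self.duration_wm_correlation) < 1:
            raise ValueError("correlation target must lie in (-1, 1)")
        if self.noise_sigma_fraction < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise model must be 'gaussian' or 'rician'")


@dataclass
class Phantom:
    """Ground-truth parameter volumes and region masks of one phantom."""

    mpf: np.ndarray          # fraction
    r1: np.ndarray
    pd: np.ndarray
    region_masks: dict       # WM / GM / PVWGM / CSF boolean volumes
    brain_mask: np.ndarray
    mix_weight: np.ndarray   # WM weight on the PVWGM shell, 0 elsewhere
    voxel_size: float = 1.25


def _elliptical_radius(shape, semi_axes):
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    a, b, c = semi_axes
    return np.sqrt((zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2)


def make_phantom(spec: PhantomSpec, subject_tissues: dict, rng_seed) -> Phantom:
    """Build a phantom from one subject's tissue parameters.

    ``subject_tissues`` maps ``"WM"``/``"GM"`` to dicts with keys ``f``
    (MPF fraction), ``r1`` and ``pd``; CSF takes the spec's fixed values.
    Voxels on the mixed shell get convex combinations
    ``w * WM + (1 - w) * GM`` with ``w`` drawn uniformly per voxel.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    rho = _elliptical_radius(spec.grid_shape, spec.semi_axes)
    e0, e1, e2, e3 = spec.rho_edges
    brain = rho <= 1.0
    masks = {
        "CSF": brain & ((rho <= e0) | (rho > e3)),
        "WM": (rho > e0) & (rho <= e1),
        "PVWGM": (rho > e1) & (rho <= e2),
        "GM": (rho > e2) & (rho <= e3),
    }
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"degenerate geometry: empty region {name}")

    f_vol = np.zeros(spec.grid_shape)
    r1_vol = np.full(spec.grid_shape, spec.r1["CSF"])
    pd_vol = np.zeros(spec.grid_shape)
    wm, gm = subject_tissues["WM"], subject_tissues["GM"]
    for name, pars in (("WM", wm), ("GM", gm)):
        f_vol[masks[name]] = pars["f"]
        r1_vol[masks[name]] = pars["r1"]
        pd_vol[masks[name]] = pars["pd"]
    f_vol[masks["CSF"]] = spec.csf_mpf
    pd_vol[masks["CSF"]] = spec.pd["CSF"]

    w = np.zeros(spec.grid_shape)
    shell = masks["PVWGM"]
    w[shell] = rng.uniform(0.0, 1.0, size=int(shell.sum()))
    f_vol[shell] = w[shell] * wm["f"] + (1 - w[shell]) * gm["f"]
    r1_vol[shell] = w[shell] * wm["r1"] + (1 - w[shell]) * gm["r1"]
    pd_vol[shell] = w[shell] * wm["pd"] + (1 - w[shell]) * gm["pd"]

    return Phantom(mpf=f_vol, r1=r1_vol, pd=pd_vol, region_masks=masks,
                   brain_mask=brain, mix_weight=w, voxel_size=spec.voxel_size)


def simulate_acquisition(phantom: Phantom, protocols: dict, noise_sigma_fraction: float,
                         rng_seed, noise_model: str = "gaussian",
                         constraints: TwoPoolConstraints | None = None) -> SourceImageSet:
    """Simulate the MTw/T1w/PDw triplet from a phantom.

    The MTw signal comes from the two-pool steady-state model; the
    T1w/PDw signals from the closed-form spoiled-GRE equation (no MT
    pulse, MT effect negligible without saturation).  Noise is additive
    Gaussian — or Rician magnitude noise — with sigma expressed as a
    fraction of the mean in-brain PDw intensity.  Seeded and
    deterministic.
    """
    if constraints is None:
        constraints = TwoPoolConstraints()
    rng = np.random.default_rng(rng_seed)
    brain = phantom.brain_mask
    r1_safe = np.where(brain, phantom.r1, 1.0)
    f_safe = np.where(brain, phantom.mpf, 0.0)

    mtw = np.zeros(brain.shape)
    mtw_b = two_pool_signal(f_safe[brain], r1_safe[brain],
                            protocols["mtw"], constraints,
                            pd=phantom.pd[brain])
    mtw[brain] = mtw_b
    t1w = np.where(brain, spoiled_gre_signal(
        phantom.pd, r1_safe, protocols["t1w"].repetition_time,
        protocols["t1w"].excitation_flip_angle), 0.0)
    pdw = np.where(brain, spoiled_gre_signal(
        phantom.pd, r1_safe, protocols["pdw"].repetition_time,
        protocols["pdw"].excitation_flip_angle), 0.0)

    sigma = noise_sigma_fraction * float(pdw[brain].mean()) if brain.any() else 0.0
    vols = []
    for vol in (mtw, t1w, pdw):
        if sigma > 0:
            if noise_model == "rician":
                n1 = rng.normal(0.0, sigma, vol.shape)
                n2 = rng.normal(0.0, sigma, vol.shape)
                vol = np.sqrt((vol + n1) ** 2 + n2 ** 2)
            else:
                vol = vol + rng.normal(0.0, sigma, vol.shape)
        vols.append(vol)
    vx = phantom.voxel_size
    return SourceImageSet(mtw=vols[0], t1w=vols[1], pdw=vols[2],
                          protocols=protocols, voxel_size=(vx, vx, vx))


def _truncated_normal(rng, mean, sd, low, high, size):
    """Draw by clipping rare out-of-range values to the bounds."""
    x = rng.normal(mean, sd, size)
    return np.clip(x, low, high)


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the cohort table of covariates and true tissue MPF.

    One row per subject with group membership, demographic and clinical
    covariates, and ground-truth per-tissue MPF (percent).  Within each
    patient subgroup, disease duration and WM MPF are drawn jointly from
    a bivariate normal hitting the target correlation in expectation;
    controls have no clinical variables.  The first ``n_rescan_controls``
    controls carry ``rescan = True``.  Durations, ages and doses are
    truncated to plausible non-negative ranges.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(seed)
    rows = []
    sizes = {"control": spec.n_control, "sz_positive": spec.n_positive,
             "sz_negative": spec.n_negative}
    rho = spec.duration_wm_correlation
    sid = 0
    for group, n in sizes.items():
        if n == 0:
            continue
        cov = spec.covariates[group]
        mpf = spec.tissue_mpf[group]
        male = rng.uniform(size=n) < cov["male_fraction"]
        gm = rng.normal(*mpf["gm_mpf"], n)
        pv = rng.normal(*mpf["pvwgm_mpf"], n)
        if group == "control":
            age = _truncated_normal(rng, *cov["age"], 18.0, 70.0, n)
            wm = rng.normal(*mpf["wm_mpf"], n)
            dur = np.full(n, np.nan)
            onset = np.full(n, np.nan)
            cpz = np.full(n, np.nan)
            panss = {k: np.full(n, np.nan) for k in
                     ("panss_positive", "panss_negative", "panss_general",
                      "panss_total")}
        else:
            # joint draw: duration and WM MPF correlated at the target rho
            z1 = rng.standard_normal(n)
            z2 = rng.standard_normal(n)
            zd = z1
            zw = rho * z1 + np.sqrt(1.0 - rho ** 2) * z2
            d_mean, d_sd = cov["disease_duration"]
            w_mean, w_sd = mpf["wm_mpf"]
            dur = np.clip(d_mean + d_sd * zd, 0.5, None)
            wm = w_mean + w_sd * zw
            onset = _truncated_normal(rng, *cov["onset_age"], 12.0, 50.0, n)
            # age follows from disease history, reproducing the group age
            # moments in expectation while keeping duration <= age
            age = np.clip(onset + dur, 18.0, 80.0)
            cpz = np.clip(rng.normal(*cov["cpz_equivalent"], n), 0.0, None)
            panss = {k: np.clip(rng.normal(*cov[k], n), 0.0, None)
                     for k in ("panss_positive", "panss_negative",
                               "panss_general", "panss_total")}
        for i in range(n):
            rows.append({
                "subject_id": f"S{sid:03d}",
                "group": group,
                "sex": "M" if male[i] else "F",
                "age": age[i],
                "onset_age": onset[i],
                "disease_duration": dur[i],
                "cpz_equivalent": cpz[i],
                **{k: panss[k][i] for k in panss},
                "gm_mpf": gm[i],
                "pvwgm_mpf": pv[i],
                "wm_mpf": wm[i],
                "rescan": group == "control" and i < spec.n_rescan_controls,
            })
            sid += 1
    return pd.DataFrame(rows)


def simulate_subject_images(row, protocols: dict,
                            phantom_spec: PhantomSpec | None = None,
                            noise_sigma_fraction: float = 0.01,
                            seed: int = 0, noise_model: str = "gaussian",
                            constraints: TwoPoolConstraints | None = None):
    """Phantom + source triplet for one cohort-table row.

    The subject's true GM/WM MPF (percent columns) set the phantom tissue
    fractions; R1 and PD come from the phantom spec.  Returns
    ``(SourceImageSet, Phantom)``.  Seeds for geometry mixing and noise
    are derived from ``seed`` so subjects are independent but
    reproducible.
    """
    if phantom_spec is None:
        phantom_spec = PhantomSpec()
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 2]).spawn(2)
    tissues = {
        "WM": {"f": float(row["wm_mpf"]) / 100.0,
               "r1": phantom_spec.r1["WM"], "pd": phantom_spec.pd["WM"]},
        "GM": {"f": float(row["gm_mpf"]) / 100.0,
               "r1": phantom_spec.r1["GM"], "pd": phantom_spec.pd["GM"]},
    }
    phantom = make_phantom(phantom_spec, tissues, ss[0])
    images = simulate_acquisition(phantom, protocols, noise_sigma_fraction,
                                  ss[1], noise_model, constraints)
    return images, phantom


def simulate_measured_means(cohort: pd.DataFrame, measurement_sd,
                            seed: int = 0, n_scans: int = 2,
                            tissues=("gm_mpf", "pvwgm_mpf", "wm_mpf")):
    """Repeated noisy measurements of the true tissue means.

    A lightweight stand-in for full scan-rescan image simulation: each
    scan adds independent Gaussian measurement error (``measurement_sd``
    per tissue, scalar or dict) to the true means.  Returns a list of
    ``n_scans`` tables aligned with ``cohort``.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(measurement_sd):
        measurement_sd = {t: float(measurement_sd) for t in tissues}
    scans = []
    for _ in range(n_scans):
        out = cohort.copy()
        for t in tissues:
            out[t] = cohort[t] + rng.normal(0.0, measurement_sd[t], len(cohort))
        scans.append(out)
    return scans
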
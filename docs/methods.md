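# Methods

This note documents the models, parameter choices and numerical decisions
behind `mpfmap`, what the synthetic data do and do not emulate, and the
known limitations.

## Two-pool signal model

Each voxel contains a free-water pool and a semisolid macromolecular pool
whose relative size is the macromolecular proton fraction *f* (reported
downstream in percent). Longitudinal magnetizations evolve under
relaxation, two-site exchange (rates *k*<sub>FB</sub> = *R f*,
*k*<sub>BF</sub> = *R*(1−*f*), equilibrium (1−*f*, *f*)·PD) and, during
the saturation pulse, pool-specific saturation rates
*W* = π ω₁ᵣₘₛ² *g*(Δ).

Modeling assumptions, each a deliberate choice where the method family
admits variants:

- **Equal pool R1.** Both pools share the observed longitudinal rate, the
  standard constraint that keeps the single-point inversion
  one-dimensional.
- **Bound-pool lineshape: super-Lorentzian** (orientation-averaged
  Gaussian), the standard semisolid model for brain tissue; a Gaussian
  lineshape is selectable through `TwoPoolConstraints` for sensitivity
  checks. The free pool uses the Lorentzian lineshape with
  T2ᶠ = (R1·T2ᶠ)/R1 re-derived per voxel from the fitted R1, which is how
  direct saturation of water enters the model.
- **Rectangular-power approximation.** The shaped pulse acts as a
  constant mean rate *W* over its duration, with ω₁ᵣₘₛ computed from the
  envelope scaled to the effective flip angle (closed erf forms for the
  truncated Gaussian; truncation level 1 % of peak by default, exposed in
  config because vendor implementations differ). Time-resolved shaped-pulse
  integration is deliberately out of scope for the production path; the
  tests keep a brute-force ODE time-stepping oracle and the matrix steady
  state agrees with it to better than 1e-6 relative.
- **Intra-TR ordering.** Saturation segment at the start of TR,
  instantaneous excitation immediately after it (free pool scaled by
  cos α, bound pool untouched), free evolution for the remainder. The
  ordering is not observable in the steady-state ratio at these segment
  durations to any relevant accuracy, but it is fixed and documented here
  rather than configurable.
- **Perfect spoiling, no echo-time decay.** All three sequences share TE,
  so T2* weighting cancels in the normalized ratio; RF-spoiling residuals
  are not modeled.
- **No B0/B1 correction** anywhere in the pipeline, matching the
  protocol's 1.5 T setting where residual field-inhomogeneity errors in
  segmented-tissue MPF are small.

The steady state is computed from closed-form 2×2 matrix exponentials
(real eigenvalues; `sinh(x)/x` series below 1e-6 for the degenerate
branch), fully vectorized over voxels.

## Reconstruction

Per brain-masked voxel: two-point VFA solution of the Ernst equation on
the PDw/T1w pair via the `S/sin α` vs `S/tan α` linearization (slope
E = e^(−TR·R1), intercept PD); synthetic no-saturation reference at the
MTw TR/flip angle; bisection on the strictly decreasing model ratio over
*f* ∈ [0, 0.35] to an absolute tolerance of 1e-5 (the bracket covers
physiological MPF with margin; the tolerance is far below noise).
Monotonicity of the ratio is asserted numerically in the tests for the
packaged protocol preset.

Degenerate inputs: voxels with non-positive signals, a VFA slope outside
(0, 1), or a normalized signal below the model value at *f* = 0.35 are
marked invalid and excluded from the validity mask. Normalized signals
*above* the model's *f* = 0 ceiling but at or below 1.05 are clamped to
*f* = 0 rather than invalidated — noise can push the measured ratio
slightly past the attainable range, and discarding those voxels would
bias tissue means upward. Signals above 1.05 are invalid. Reconstruction
is deterministic and bit-reproducible.

## Segmentation

The paper-style four classes (WM, GM, mixed WM/GM, CSF partial volume)
are obtained from a transparent 1-D Gaussian-mixture EM on the map values
above the 1 % MPF threshold (strict inequality; boundary voxels are
excluded). Component means initialize at the 13/6/9/1 % tissue priors,
interpreted here as initial class centers in percent MPF; weights start
equal and variances at sample-variance/4. Convergence at log-likelihood
gain < 1e-6 or 200 iterations; voxels are assigned by maximum posterior.

This deliberately replaces an image-space segmenter with spatial priors:
the downstream statistics consume means over large masks, for which an
intensity mixture with the same initialization is sufficient, fully
reproducible, and auditable. An optional iterated-conditional-modes pass
(6-neighborhood Potts prior, β configurable) adds spatial smoothing and
is off by default, since mask-mean statistics are second-order in it.

Numerical guards: effectively empty components are re-seeded at their
prior with a floor variance and flagged; point-mass components only have
their variance floored (re-seeding them would destroy exact fits on
noiseless data). After fitting, components are matched to classes by
nearest initial mean, greedily from the closest pair, matching healthy
components before collapsed ones — a global assignment can otherwise let
a spurious duplicate steal a well-anchored class. Components that merge
onto the same mode (final means closer than 1 pp) are flagged as
degenerate, with the lighter of the pair marked.

Known limitation: on a partial-volume shell whose values are uniform
mixtures of WM and GM, hard maximum-posterior assignment trims both tails
of the band asymmetrically; the recovered mixed-class mean carries a
small negative bias (≈0.14 pp at the default geometry and 1 % noise).
WM/GM means are unaffected to within a few hundredths of a percentage
point, and the bias stays within two standard errors of the generating
group distributions at the study's group sizes.

## Calibration and effect measures

Myelin density MD = (MPF − 3.9)/0.21, percent units on both sides, with
coefficients configurable. Values below the intercept extrapolate
negative and are left to the caller to flag. Summaries round myelin
densities to one decimal and relative MPF decreases to integers —
matching the field's reporting convention — while machine-readable
outputs always carry the raw values. Cohen's d uses the pooled-SD form
with the reference-minus-comparison sign convention.

## Cohort statistics

- Shapiro–Wilk normality per group × tissue (3 ≤ n ≤ 5000; constant
  samples rejected).
- MANCOVA of the three tissue means on group plus age: Wilks
  Λ = det(E)/det(E+H) with E the full-model residual SSCP and H the
  extra residual SSCP when a term is dropped (Type-III-style, treatment
  coding with controls as reference); Rao's F approximation for the
  p-value, which is exact whenever min(responses, hypothesis df) ≤ 2 —
  satisfied here, with three responses against one- or two-df
  hypotheses. Null simulations confirm uniform p-values.
- Tukey HSD adjusted pairwise p-values (Tukey–Kramer under unequal n),
  computed through statsmodels behind the module surface.
- Pearson correlations, and age-adjusted partial correlations from the
  closed form (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) with t on n−3 df;
  the tests verify exact agreement with the residual-regression identity.
- Repeatability: Bland–Altman bias and 1.96·SD limits of agreement,
  paired t, within-subject SD √(Σd²/2n) and CoV = 100·SD_w/grand mean.
- Two-tailed tests at α = 0.05 throughout; no multiplicity control beyond
  Tukey. Clinical-variable correlations run within the patient group;
  age correlations additionally within controls.

## Synthetic data

The phantom is an abstract nested-ellipsoid brain (CSF core, WM core,
mixed WM/GM shell with per-voxel uniform mixing weights, GM shell, CSF
rim) on a 48³ grid of 1.25 mm voxels by default — anatomy is irrelevant
to mask-mean statistics, and the small grid keeps a 54-subject cohort run
in the low minutes; full-size grids are supported via the spec. Tissue
R1 (WM 1.5, GM 0.9, CSF 0.25 s⁻¹) and proton densities (0.7/0.85/1.0)
are typical 1.5 T magnitudes; they shape realism, not the acceptance
math, and are fully exposed in the spec.

Cohorts default to the study composition (23 controls, 10 patients with
leading positive symptoms, 21 with negative symptoms; 8 controls
rescanned). Covariates draw from the published group moments, truncated
to plausible ranges. Within each patient subgroup, disease duration and
WM MPF draw jointly from a bivariate normal at the target correlation
−0.51; patient age is then onset age + duration, which reproduces the
group age moments in expectation while guaranteeing duration ≤ age and
leaving the duration–WM coupling intact (truncating age independently
was found to attenuate the correlation). Pooling the two patient
subgroups adds a between-group component, so the pooled patient
correlation runs slightly stronger than the within-group target. PANSS
scores are decorative covariates drawn from subgroup moments; controls
carry none.

Noise is additive Gaussian (or optional Rician magnitude noise) with σ
expressed as a fraction of the mean in-brain PDw intensity, 1 % by
default. All generators are seeded; identical spec + seed reproduces
outputs bit-for-bit, noise included.

What passing phantom tests do **not** show about real data: no motion,
bias fields, registration error, anatomical partial-volume geometry,
iron-related relaxation variation, or scanner drift are modeled. The
scan-rescan CoV of the image-level pipeline (≈0.03 %) therefore reflects
thermal noise only and is far below in vivo repeatability figures, which
are dominated by repositioning and physiology; the repeatability module
is validated on its mechanics (bias, limits of agreement, CoV tracking
100·σ/mean), not on reproducing in vivo CoV magnitudes. Likewise, the
real study's exact test statistics are not reproducible without the raw
scans; the statistics are validated by null-calibration and power
properties at the published group moments instead.

## Problem sizes

Defaults used by the test suite and the acceptance script: 48³ phantoms
(≈37k brain voxels), 54-subject cohorts, 500 null-simulation seeds for
p-value calibration, 200 seeds for power and correlation summaries, and
18 (f, R1) grid points for the roundtrip check. These sizes make the full
validation run in a few minutes while leaving Monte-Carlo error well
below the tolerances being asserted.
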
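# mpfmap

Quantitative myelin imaging by fast **macromolecular proton fraction (MPF)
mapping**, implemented end-to-end as a tested Python library: the two-pool
pulsed magnetization-transfer (MT) signal model, single-point
synthetic-reference MPF reconstruction from three spoiled gradient-echo
volumes, prior-initialized tissue segmentation of MPF maps, MPF-to-myelin-
density calibration, and the cohort statistics used in clinical
hypomyelination studies — all exercised on synthetic digital phantoms and
synthetic cohorts with known ground truth.

The package is aimed at researchers who want a transparent, reproducible
reference implementation of the MPF mapping pipeline: to study its error
propagation, validate processing choices on phantoms, or power synthetic
cohort analyses before acquiring clinical data.

## The model

Brain tissue is modeled as two exchanging proton pools — free water and a
semisolid macromolecular pool of relative size *f* (the MPF). Under an
off-resonance saturation pulse (offset Δ, RMS amplitude ω₁ᵣₘₛ), each pool
is saturated at rate

&nbsp;&nbsp;&nbsp;&nbsp;*W = π ω₁ᵣₘₛ² g(Δ)*,

with a Lorentzian absorption lineshape *g* for water and a
super-Lorentzian for the semisolid pool. The coupled longitudinal
magnetizations evolve piecewise over each TR (saturation segment →
instantaneous excitation by α → free recovery), with exchange rates
*k*<sub>FB</sub> = *R f*, *k*<sub>BF</sub> = *R*(1−*f*); the periodic
steady state solves a 2×2 linear fixed point. With no saturation and
*f* = 0 the signal reduces to the Ernst spoiled-GRE equation
*S* = PD·sin α (1−E)/(1−E cos α), E = e^(−TR·R1).

Single-point reconstruction fixes the remaining two-pool parameters at
literature constraints (*R* = 19 s⁻¹, T2ᴮ = 10 μs, R1·T2ᶠ = 0.055),
fits R1 and PD from the T1w/PDw pair by the two-point variable-flip-angle
(VFA) solution, computes a synthetic no-saturation reference at the MTw
sequence settings, and inverts the strictly monotone normalized signal
ratio for *f* per voxel. Tissue means come from a four-class EM mixture
segmentation of the map (WM, GM, mixed WM/GM, CSF partial volume,
initialized at 13/6/9/1 % MPF; MPF > 1 % threshold), and myelin density
follows the histological calibration **MPF = 0.21 × MD + 3.9** (percent
units).

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_reconstruct_phantom.py` simulates a 48³ digital brain
phantom, acquires the MTw/T1w/PDw triplet with 1 % noise and reconstructs
the map:

```
brain voxels: 37296, invalid after inversion: 0 (0.00%)
per-voxel error: median |err| 0.102 pp, 95th percentile 0.401 pp
WM: region mean 13.041% vs truth 13.040% (bias +0.0014 pp)
GM: region mean 6.442% vs truth 6.440% (bias +0.0021 pp)
```

Per-voxel noise of a few tenths of a percentage point averages away over
tissue regions: group-level analyses operate on region means accurate to
hundredths of a percentage point. `examples/03_segment_and_calibrate.py`
continues to segmentation and calibration:

```
WM: mean MPF 13.01% -> myelin density 43.4%
GM: mean MPF 6.45% -> myelin density 12.1%
PVWGM: mean MPF 9.64% -> myelin density 27.3%
```

and `examples/04_cohort_statistics.py` runs the statistical battery
(MANCOVA with age covariate, Tukey HSD, effect sizes, age-adjusted
partial correlations) over a synthetic 54-subject cohort.

A thin command-line interface wires the same stages file-to-file over
NIfTI/CSV/JSON artifacts:

```bash
mpfmap simulate   --out run/sim --seed 1
mpfmap reconstruct --input run/sim --out run/maps
mpfmap segment    --input run/sim --maps run/maps --out run/seg
mpfmap analyze    --cohort run/seg/cohort_measured.csv \
                  --measured run/seg/measured_tissue_means.csv --out run/stats
```

## Layout

- `src/mpfmap/model.py` — lineshapes, pulse power, two-pool steady state
- `src/mpfmap/reconstruct.py` — VFA fit, synthetic reference, inversion
- `src/mpfmap/segment.py` — EM tissue segmentation, tissue means
- `src/mpfmap/calibration.py` — myelin density, percent change, Cohen's d
- `src/mpfmap/stats.py` — MANCOVA, Tukey HSD, correlations, repeatability
- `src/mpfmap/synthetic.py` — phantoms and cohort generation
- `src/mpfmap/pipeline.py`, `src/mpfmap/cli.py` — orchestration
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
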
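# Methods

## Setting and model

Each QA session yields one signed couch offset per axis (IEC X/Y/Z,
millimetres, deviation from a calibrated baseline). The in-control model is
that successive offsets are independent draws from a stationary normal
distribution N(μ, σ²) with σ between roughly 0.17 and 0.55 mm depending on
unit and axis. Two families of departures matter clinically and are modelled
explicitly:

* **setup errors** — isolated outliers (> 1 mm) from phantom mis-positioning;
  random causes that should not, by themselves, trigger remediation;
* **systematic faults** — sustained mean shifts or drifts (e.g. a failing
  couch-axis encoder) that persist until repaired.

All chart math treats the series as exchangeable within a window; serial
correlation from slow drifts is exactly what the trend layer is meant to
surface, not something the in-control model absorbs.

## Individuals chart

Dispersion is estimated from span-2 moving ranges: E(mR) = d₂·σ with
d₂(2) = 2/√π ≈ 1.12838. We use the exact constant rather than the tabulated
1.128; for subgroup sizes 3–10, `d2_constant` evaluates
∫[1 − Φ(x)ᵐ − (1−Φ(x))ᵐ]dx by adaptive quadrature. Limits are
CL ± 3·mR̄/(d₂√n) with n = 1. Conventions fixed for testability:

* a point exactly on a limit is **in control** (strict inequality for
  violations), likewise for the action band;
* a constant series yields UCL = CL = LCL with a warning, not an error;
* limits default to the retrospective (Phase-I) estimate from the series
  itself; monitoring against an independent baseline is done by passing that
  baseline's limits to `flag_points` or by `compare_phases`;
* only the basic out-of-control rule (point beyond 3σ limits) is applied; run
  rules are deliberately omitted because sustained runs are handled by
  window means and phase comparison instead;
* out-of-control points are not purged before limit computation (no
  iterative re-estimation) — retrospective analyses keep all data.

## Normality testing

The Anderson–Darling statistic is evaluated literally from the ordered
sample with the hypothesized normal CDF clamped to [1e−16, 1 − 1e−16] before
taking logarithms; the clamp is part of the statistic's numerical definition
(it only matters for order statistics beyond ~8σ and its effect is below
any test tolerance). For the composite null both parameters are estimated
from the sample (mean, SD with n − 1), the statistic is modified by
(1 + 0.75/n + 2.25/n²), and the p-value uses Stephens' four-piece
exponential approximation. The test refuses n < 8 (approximation floor) and
zero-variance samples. Ties are allowed and handled by stable sorting. Our
implementation agrees with `statsmodels.stats.diagnostic.normal_ad` to
1e−10 on the statistic; that library is used in the test suite only, as an
independent oracle.

## Capability

σ in cp/cpk is the **overall** sample SD of the window (the "data
distribution" dispersion), not the within/moving-range estimate — both are
reported (`sigma` vs `sigma_within`), and in the process-index literature
the overall-σ variants are often written Pp/Ppk; we keep the cp/cpk names
used in routine machine-QA practice. The acceptability threshold is 1.0 for
both indices; no confidence intervals are attached because the indices are
used here as descriptive window summaries.

## Windowing and phase comparison

Windows are index-based, non-overlapping, 90 observations by default (≈ 3
months at a daily test cadence). A trailing partial window is reported (its
chart lines and flags are still computed; for a single-point remainder the
chart degenerates to CL = UCL = LCL) but excluded from normality and
capability, where small n distorts both. Mean variation is the window CL
minus a baseline reference, 0 mm by default since offsets are deviations
from baseline by construction.

`compare_phases` learns limits on the *before* phase and judges the *after*
phase against them. The verdict is `systematic_shift` when |ΔCL| exceeds the
drift threshold (default 0.5 mm, the magnitude at which quarterly mean
wander becomes clinically interesting; a tunable, not a claim) **or at
least two** after-phase points fall outside the before-phase limits. The
two-point floor is a deliberate design choice: with 90-point phases, a
single escape has probability ≈ 1 − 0.9973⁹⁰ ≈ 0.22 under the in-control
model, so an any-point rule would flag a fifth of healthy quarters, and an
isolated escape is the signature of a setup error (random cause), not of a
systematic fault. Requiring two escapes puts the false-flag probability
near 2–3% while a genuine 1 mm step at σ = 0.3 mm pushes dozens of points
out. The `limits_respected_in_b` field still reports the literal
all-points-inside fact.

## Offset recovery

Replicates are averaged per applied value before comparison. The on-axis
deviation at applied shift a is mean(detected) − a; the verdict carries the
worst one and its applied value. Cross-axis coupling is reported only where
it is detectable: applied shifts with |a| ≥ 2 mm (smaller shifts drown in
measurement noise) whose mean off-axis response exceeds 3× the ±0.2 mm
reproducibility. `cross_axis_matrix` gives the complete picture as OLS
slopes of each detected axis against each applied axis; an ideal system is
the identity matrix, an on-axis detection bias shows as a diagonal entry ≠ 1
and cobra coupling as a (Z, Y) off-diagonal. Linearity fits are ordinary
least squares; a constant response is defined to have R² = 0, and designs
with fewer than three distinct applied values are rejected.

## Synthetic generator

`generate_series` draws the in-control core iid N(mean, sd²), then (in
order) replaces a contamination fraction with uniform draws if requested,
replaces outlier-sampled points with sign-random magnitudes
U(scale, scale + 1) mm (scale > 1 mm, so every outlier is a bona-fide setup
error), and adds fault-segment shifts/drifts. Timestamps are synthesized at
a daily 09:00 cadence from 2013-01-01 — this affects only the time column,
never the statistics. Randomness is NumPy `default_rng` (PCG64), so a given
spec + seed is bit-reproducible on any platform; cross-language
re-implementations should compare statistically, not bit-wise.

The shipped "T1"/"T2" presets place each axis at its published three-monthly
operating point (CL, σ); the 4-year archive lengths are 1530 and 1388
observations. What the generator does **not** emulate: serial correlation of
real QA drift (faults are piecewise-deterministic, not stochastic
processes), rounding of the machine's reported offsets, operator-dependent
heteroscedasticity, and any couch kinematics — so a passing suite shows the
*statistical machinery* is correct and calibrated, not that real archives
are this well behaved.

`generate_experiment` produces detected = applied·(1 + bias slope) + noise
on-axis and coupling-slope·applied + noise off-axis, with a vertical bias
slope of 1.19/5 per mm (worst error +1.19 mm at +5 mm applied), Z→Y coupling
slope 0.234 (≈ 1.17 mm at 5 mm), per-read noise SD 0.2/3 mm so replicate
spread is ≈ ±0.2 mm, and a gantry-phase response of 0.5°/mm to lateral
shifts with noise SD 0.087° chosen so the phase linearity sits near
R² = 0.996 over the default grid.

## Problem sizes and calibration checks

The calibration suite uses 10,000-point runs for chart coverage (limits
learned on one run, coverage measured on an independent one), 2,000
replicates of n = 90 for the AD type-I error, 200 seeds for step-change
detection/false-alarm rates and for the capability-pattern reproduction, and
25 replicates for bias recovery — sizes at which Monte-Carlo error is
comfortably inside each check's tolerance while the whole suite runs in
seconds. For the capability pattern, cells whose true ±1 mm cp lies within
~2 sampling standard errors of 1.0 at n = 90 (the T1 lateral and vertical
axes, cp 0.970 and 0.884) are asserted on the closed form of the indices
rather than per-seed: no estimator can reproduce a verdict in ≥95% of seeds
when the truth sits essentially on the decision boundary, which is precisely
why such axes are called "borderline" in practice.

## Known limitations

* Individuals charts assume approximate normality; the AD verdict is
  reported alongside precisely because heavy contamination biases mR̄-based
  limits. No robust (median-mR) variant is provided.
* No EWMA/CUSUM or run rules, and no automatic change-point search — faults
  are localized by window/phase structure, with event indices supplied by
  the user where known.
* Capability indices on non-normal windows are descriptive only; no
  percentile-based non-normal variants.
* The CSV dialect is fixed (comma, UTF-8, ISO timestamps); no vendor export
  parsing or DICOM.
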
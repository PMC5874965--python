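"""Synthetic QA logs and offset experiments with known ground truth.

Real couch-offset QA archives are clinic-internal, so every analysis in this
package is exercised on simulated data whose statistical structure matches
what such logs look like in practice:

* an in-control core of iid Gaussian offsets per (unit, axis), with the
  per-axis mean and dispersion of the shipped "T1"/"T2" presets set to the
  published three-monthly center lines and standard deviations
  (σ ≈ 0.17–0.55 mm);
* sporadic setup-error outliers (isolated phantom mis-positions > 1 mm);
* sustained fault segments — a constant shift or a linear drift — emulating
  encoder faults that push the process out of control until recalibrated;
* an optional uniform-mixture contamination that defeats a normality test
  without moving mean or scale much.

Every generated point carries a ground-truth label (in-control / outlier /
fault-segment id), so detection tests can score against truth rather than
against the generator's own statistics.  Randomness comes from NumPy's
``default_rng`` (PCG64); identical spec + seed reproduces output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from .qa_log_io import AXES, OffsetTrial, QARecord, QASeries

#: three-monthly (90-observation) center line and sigma per unit/axis, mm —
#: the published operating points of the two clinical units
PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "T1": {"IECX": (-0.062, 0.3436), "IECY": (-0.039, 0.165), "IECZ": (-0.366, 0.377)},
    "T2": {"IECX": (0.046, 0.295), "IECY": (0.174, 0.171), "IECZ": (-0.880, 0.542)},
}

#: 4-year observation counts of the two units
FOUR_YEAR_N = {"T1": 1530, "T2": 1388}

DEFAULT_START_DATE = date(2013, 1, 1)


@dataclass(frozen=True)
class FaultSegment:
    """A sustained systematic disturbance over [start, end) indices: a
    constant ``shift_mm`` and/or a linear drift accumulating
    ``drift_per_obs_mm`` per observation from the segment start."""

    start: int
    end: int
    shift_mm: float = 0.0
    drift_per_obs_mm: float = 0.0


@dataclass(frozen=True)
class SeriesSpec:
    unit_id: str = "T1"
    axis: str = "IECX"
    n: int = 90
    mean_mm: float = 0.0
    sd_mm: float = 0.3
    outlier_rate: float = 0.0
    outlier_scale_mm: float = 1.5  # setup errors are > 1 mm by definition
    fault_segments: tuple[FaultSegment, ...] = ()
    contamination: str = "none"  # none | uniform_mixture
    contamination_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_mm <= 0:
            raise ValueError("sd_mm must be > 0")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.outlier_rate > 0 and self.outlier_scale_mm <= 1.0:
            raise ValueError("outlier_scale_mm must exceed 1 mm (setup errors are > 1 mm)")
        if self.contamination not in ("none", "uniform_mixture"):
            raise ValueError(f"unknown contamination {self.contamination!r}")
        last_end = 0
        for seg in sorted(self.fault_segments, key=lambda s: s.start):
            if not (0 <= seg.start < seg.end <= self.n):
                raise ValueError(f"fault segment [{seg.start}, {seg.end}) outside [0, {self.n})")
            if seg.start < last_end:
                raise ValueError("fault segments must not overlap")
            last_end = seg.end


@dataclass(frozen=True)
class GroundTruth:
    """Per-point labels: which points are clean, which were replaced by
    outliers/contamination, and which fault segment (if any) covers them."""

    in_control: np.ndarray  # bool
    outlier: np.ndarray  # bool
    fault_segment_id: np.ndarray  # int, -1 where no segment applies


def _timestamps(n: int, start: date = DEFAULT_START_DATE) -> list[str]:
    # daily cadence: 90 observations ≈ three months of daily QA
    return [(start + timedelta(days=i)).isoformat() + "T09:00:00" for i in range(n)]


def generate_series(spec: SeriesSpec) -> tuple[QASeries, GroundTruth]:
    """Simulate one (unit, axis) QA series with ground-truth annotation."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    x = rng.normal(spec.mean_mm, spec.sd_mm, size=n)
    outlier = np.zeros(n, dtype=bool)
    fault_id = np.full(n, -1, dtype=int)

    if spec.contamination == "uniform_mixture":
        k = int(round(spec.contamination_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        x[idx] = rng.uniform(
            spec.mean_mm - 3 * spec.sd_mm, spec.mean_mm + 3 * spec.sd_mm, size=k
        )
        # contamination keeps mean/scale but breaks the normal shape; the
        # affected points are still "in control" for charting purposes

    if spec.outlier_rate > 0:
        hits = rng.random(n) < spec.outlier_rate
        mags = rng.uniform(spec.outlier_scale_mm, spec.outlier_scale_mm + 1.0, size=n)
        signs = rng.choice([-1.0, 1.0], size=n)
        x[hits] = spec.mean_mm + signs[hits] * mags[hits]
        outlier |= hits

    for sid, seg in enumerate(spec.fault_segments):
        sl = slice(seg.start, seg.end)
        idx = np.arange(seg.end - seg.start)
        x[sl] += seg.shift_mm + seg.drift_per_obs_mm * idx
        fault_id[sl] = sid

    truth = GroundTruth(
        in_control=(~outlier) & (fault_id < 0),
        outlier=outlier,
        fault_segment_id=fault_id,
    )
    series = QASeries(
        unit_id=spec.unit_id, axis=spec.axis, values=x, timestamps=_timestamps(n)
    )
    return series, truth


def preset_spec(unit_id: str, axis: str, n: int | None = None, seed: int = 0, **overrides) -> SeriesSpec:
    """SeriesSpec parameterized at a shipped preset's (CL, σ) operating point."""
    cl, sigma = PRESETS[unit_id][axis]
    if n is None:
        n = 90
    return replace(
        SeriesSpec(unit_id=unit_id, axis=axis, n=n, mean_mm=cl, sd_mm=sigma, seed=seed),
        **overrides,
    )


def series_to_records(series: QASeries) -> list[QARecord]:
    """Expand a series into writable QARecords (for CSV export)."""
    ts = series.timestamps or _timestamps(series.n)
    return [
        QARecord(timestamp=t, unit_id=series.unit_id, axis=series.axis, offset_mm=float(v))
        for t, v in zip(ts, series.values)
    ]


# ---------------------------------------------------------------------------
# applied-offset experiments


@dataclass(frozen=True)
class ExperimentSpec:
    """Generator settings for an applied-vs-detected offset experiment.

    Defaults mirror the bench protocol: shifts of ±0.5/±1/±2/±5 mm on each
    axis, three replicates each, per-read noise such that replicate spread is
    ≈ ±0.2 mm, a vertical (Z) detection bias growing linearly to +1.19 mm at
    +5 mm applied, cobra coupling of Z shifts into the detected Y offset
    (slope 0.234), and a gantry-phase response to lateral (X) shifts whose
    noise level puts the phase-vs-applied linearity near R² = 0.996.
    """

    applied_grid_mm: tuple[float, ...] = (-5.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 5.0)
    replicates: int = 3
    reproducibility_sd_mm: float = 0.2 / 3.0  # 3 sigma ≈ ±0.2 mm replicate spread
    on_axis_bias_slope: dict = field(
        default_factory=lambda: {"IECX": 0.0, "IECY": 0.0, "IECZ": 1.19 / 5.0}
    )
    coupling: tuple[tuple[str, str, float], ...] = (("IECZ", "IECY", 0.234),)
    phase_slope_deg_per_mm: float = 0.5
    phase_noise_sd_deg: float = 0.087
    energy_noise_sd_pct: float = 0.1
    output_noise_sd_pct: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.reproducibility_sd_mm <= 0:
            raise ValueError("reproducibility_sd_mm must be > 0")
        for src, tgt, _ in self.coupling:
            if src not in AXES or tgt not in AXES or src == tgt:
                raise ValueError(f"invalid coupling pair ({src}, {tgt})")


def generate_experiment(spec: ExperimentSpec) -> tuple[list[OffsetTrial], dict]:
    """Simulate the full experiment grid; returns trials plus the injected
    ground truth (bias slopes and coupling table)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    coupling_map = {(s, t): c for s, t, c in spec.coupling}
    trials = []
    for axis in AXES:
        ax_i = AXES.index(axis)
        for applied in spec.applied_grid_mm:
            for rep in range(1, spec.replicates + 1):
                detected = np.zeros(3)
                for tgt_i, tgt in enumerate(AXES):
                    if tgt_i == ax_i:
                        signal = applied * (1.0 + spec.on_axis_bias_slope.get(axis, 0.0))
                    else:
                        signal = coupling_map.get((axis, tgt), 0.0) * applied
                    detected[tgt_i] = signal + rng.normal(0.0, spec.reproducibility_sd_mm)
                phase = (
                    spec.phase_slope_deg_per_mm * applied
                    + rng.normal(0.0, spec.phase_noise_sd_deg)
                    if axis == "IECX"
                    else rng.normal(0.0, spec.phase_noise_sd_deg)
                )
                trials.append(
                    OffsetTrial(
                        axis=axis,
                        applied_mm=float(applied),
                        detected_mm=tuple(float(v) for v in detected),
                        energy_pct=float(rng.normal(0.0, spec.energy_noise_sd_pct)),
                        output_pct=float(rng.normal(0.0, spec.output_noise_sd_pct)),
                        gantry_phase_deg=float(phase),
                        replicate=rep,
                    )
                )
    truth = {
        "on_axis_bias_slope": dict(spec.on_axis_bias_slope),
        "coupling": {f"{s}->{t}": c for (s, t), c in coupling_map.items()},
        "phase_slope_deg_per_mm": spec.phase_slope_deg_per_mm,
    }
    return trials, truth
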
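"""Whole-log analysis: configuration, report assembly, recommendation.

`run_full_analysis` ties the pipeline together the way a routine (e.g.
three-monthly) QA review would: for every requested (unit, axis) it windows
the series, computes control limits, flags, normality and capability per
window, compares consecutive full windows for systematic shifts, and emits a
single machine-readable report with an overall recommendation driven solely
by the computed flags.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .capability import SpecLimits
from .errors import ConfigError
from .normality import ADResult
from .qa_log_io import AXES, read_qa_log, to_series
from .trend_analysis import (
    DEFAULT_DRIFT_THRESHOLD_MM,
    DEFAULT_WINDOW_SIZE,
    WindowReport,
    compare_phases,
    analyze_windows,
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Validated settings for a full-log analysis run."""

    input: str
    units: list[str] | None = None  # None = every unit present in the log
    axes: list[str] | None = None  # None = all three IEC axes
    window_size: int = DEFAULT_WINDOW_SIZE
    action_limits_mm: list[float] = field(default_factory=lambda: [1.0, 2.0])
    alpha: float = 0.05
    tolerance_mm: float = 2.0  # action level used for point flagging
    drift_threshold_mm: float = DEFAULT_DRIFT_THRESHOLD_MM
    baseline_reference_mm: float = 0.0
    seed: int | None = None
    output: str | None = None

    _FIELDS = (
        "input",
        "units",
        "axes",
        "window_size",
        "action_limits_mm",
        "alpha",
        "tolerance_mm",
        "drift_threshold_mm",
        "baseline_reference_mm",
        "seed",
        "output",
    )

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.window_size < 8:
            raise ConfigError(f"window_size must be >= 8, got {self.window_size}")
        if self.tolerance_mm <= 0:
            raise ConfigError(f"tolerance_mm must be > 0, got {self.tolerance_mm}")
        if self.drift_threshold_mm <= 0:
            raise ConfigError(f"drift_threshold_mm must be > 0, got {self.drift_threshold_mm}")
        if not self.action_limits_mm or any(a <= 0 for a in self.action_limits_mm):
            raise ConfigError("action_limits_mm must be a non-empty list of positive half-widths")
        if self.axes is not None:
            bad = [a for a in self.axes if a not in AXES]
            if bad:
                raise ConfigError(f"unknown axes: {bad}")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        unknown = set(data) - set(cls._FIELDS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "input" not in data:
            raise ConfigError("config requires an 'input' path")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def _ad_to_dict(ad: ADResult | None):
    if ad is None:
        return None
    return {
        "A2": ad.A2,
        "A2_star": ad.A2_star,
        "p_value": ad.p_value,
        "h": ad.h,
        "n": ad.n,
    }


def window_report_to_dict(w: WindowReport) -> dict:
    return {
        "window_index": w.window_index,
        "start": w.start,
        "end": w.end,
        "partial": w.partial,
        "n": w.end - w.start,
        "CL": w.limits.CL,
        "UCL": w.limits.UCL,
        "LCL": w.limits.LCL,
        "mR_bar": w.limits.mR_bar,
        "sigma_within": w.limits.sigma_within,
        "mean_variation_mm": w.mean_variation_mm,
        "n_beyond_spc": w.n_beyond_spc,
        "n_beyond_action": w.n_beyond_action,
        "ad": _ad_to_dict(w.ad),
        "capability": [
            {
                "usl": c.spec.USL,
                "lsl": c.spec.LSL,
                "cp": c.cp,
                "cpk": c.cpk,
                "sigma": c.sigma,
                "mean": c.mean,
                "acceptable": c.acceptable,
            }
            for c in w.capability
        ],
    }


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute the whole pipeline for one log; returns the report document.

    The report's ``exit_code`` is 0 iff no (unit, axis) shows a systematic
    shift between consecutive full analysis windows.
    """
    records = read_qa_log(config.input)
    units = config.units or sorted({r.unit_id for r in records})
    axes = config.axes or list(AXES)
    specs = [SpecLimits.symmetric(a) for a in config.action_limits_mm]

    series_reports = []
    any_shift = False
    any_action_breach = False
    for unit in units:
        for axis in axes:
            if not any(r.unit_id == unit and r.axis == axis for r in records):
                continue
            series = to_series(records, unit, axis)
            windows = analyze_windows(
                series,
                specs,
                window_size=config.window_size,
                baseline_reference=config.baseline_reference_mm,
                alpha=config.alpha,
                action_limit_mm=config.tolerance_mm,
            )
            full = [w for w in windows if not w.partial]
            shifts = []
            for a, b in zip(full, full[1:]):
                cmp = compare_phases(
                    series.slice(a.start, a.end),
                    series.slice(b.start, b.end),
                    specs,
                    drift_threshold_mm=config.drift_threshold_mm,
                    alpha=config.alpha,
                    action_limit_mm=config.tolerance_mm,
                )
                shifts.append(
                    {
                        "from_window": a.window_index,
                        "to_window": b.window_index,
                        "delta_CL": cmp.delta_CL,
                        "n_b_beyond_a_limits": cmp.n_b_beyond_a_limits,
                        "verdict": cmp.verdict,
                    }
                )
            systematic = any(s["verdict"] == "systematic_shift" for s in shifts)
            any_shift |= systematic
            any_action_breach |= any(w.n_beyond_action > 0 for w in windows)
            series_reports.append(
                {
                    "unit_id": unit,
                    "axis": axis,
                    "n": series.n,
                    "windows": [window_report_to_dict(w) for w in windows],
                    "phase_comparisons": shifts,
                    "systematic_shift": systematic,
                }
            )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("output",)
        },
        "series": series_reports,
        "recommendation": (
            "investigate" if (any_shift or any_action_breach) else "within control"
        ),
        "exit_code": 1 if any_shift else 0,
    }
    if config.output:
        with open(config.output, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    return report
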
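"""Windowed ("three-monthly") trend analysis and pre/post-remediation comparison.

A long QA series is partitioned into consecutive non-overlapping windows of
90 observations (one window ≈ three months at a daily test cadence).  Each
window gets its own control limits, normality verdict, capability indices at
every configured action level, and a mean-variation figure (window mean minus
the baseline reference, 0 mm by construction for offset data).

`compare_phases` reproduces the before/after-remediation logic: limits are
computed on the *before* phase, the *after* phase is judged against them, and
a systematic shift is declared when the after-phase mean drifts beyond a
threshold or more than one after-phase point escapes the before-phase
limits.  A single escaped point is treated as an isolated setup error
(random cause), not a systematic shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capability import CapabilityResult, SpecLimits, assess_capability
from .control_charts import ControlLimits, chart_limits, flag_points
from .errors import InsufficientDataError
from .normality import ADResult, MIN_N_FOR_TEST, ad_test
from .qa_log_io import QASeries

DEFAULT_WINDOW_SIZE = 90  # observations; ≈ 3 months at daily cadence
DEFAULT_DRIFT_THRESHOLD_MM = 0.5

#: after-phase points beyond before-phase limits needed to call a shift;
#: one isolated violation is a setup error, not a regime change
MIN_VIOLATIONS_FOR_SHIFT = 2


@dataclass(frozen=True)
class WindowSlice:
    """One partition window: the sub-series plus its position in the parent."""

    series: QASeries
    start: int
    end: int  # half-open [start, end)
    partial: bool


@dataclass(frozen=True)
class WindowReport:
    window_index: int
    start: int
    end: int
    partial: bool
    limits: ControlLimits
    ad: ADResult | None  # None for partial/short windows
    capability: list[CapabilityResult]  # one per configured SpecLimits
    mean_variation_mm: float
    n_beyond_spc: int
    n_beyond_action: int


@dataclass(frozen=True)
class PhaseComparison:
    phase_a: WindowReport
    phase_b: WindowReport
    delta_CL: float
    limits_respected_in_b: bool  # literally: every phase-b point inside phase-a limits
    n_b_beyond_a_limits: int
    verdict: str  # stable | systematic_shift


def partition_windows(series: QASeries, window_size: int = DEFAULT_WINDOW_SIZE) -> list[WindowSlice]:
    """Consecutive non-overlapping windows; a trailing partial window is
    returned flagged rather than dropped, so window sizes sum to n."""
    if window_size < MIN_N_FOR_TEST:
        raise ValueError(f"window_size must be >= {MIN_N_FOR_TEST}, got {window_size}")
    out = []
    n = series.n
    for start in range(0, n, window_size):
        end = min(start + window_size, n)
        out.append(
            WindowSlice(
                series=series.slice(start, end),
                start=start,
                end=end,
                partial=(end - start) < window_size,
            )
        )
    return out


def analyze_window(
    window: QASeries | WindowSlice,
    specs: list[SpecLimits],
    baseline_reference: float = 0.0,
    alpha: float = 0.05,
    action_limit_mm: float = 2.0,
    window_index: int = 0,
) -> WindowReport:
    """Full per-window report: chart limits, flags, normality, capability.

    Partial windows keep their chart and flag statistics but skip the AD test
    and capability indices (too few points for either to be meaningful).
    """
    if isinstance(window, WindowSlice):
        ws = window
    else:
        ws = WindowSlice(series=window, start=0, end=window.n, partial=False)
    series = ws.series
    if series.n < 2:
        if not ws.partial:
            raise InsufficientDataError(
                f"window {window_index}: need at least 2 observations"
            )
        # single-point trailing window: chart collapses onto the point
        from .control_charts import d2_constant

        v = float(series.values[0])
        limits = ControlLimits(
            CL=v, UCL=v, LCL=v, d2=d2_constant(2), n_sub=1, mR_bar=0.0, sigma_within=0.0
        )
    else:
        limits = chart_limits(series)
    summary = flag_points(series, limits, action_limit_mm=action_limit_mm)
    run_full_stats = not ws.partial and series.n >= MIN_N_FOR_TEST
    ad = None
    capability: list[CapabilityResult] = []
    if run_full_stats:
        ad = ad_test(series.values, alpha=alpha)
        capability = [assess_capability(series, spec) for spec in specs]
    return WindowReport(
        window_index=window_index,
        start=ws.start,
        end=ws.end,
        partial=ws.partial,
        limits=limits,
        ad=ad,
        capability=capability,
        mean_variation_mm=float(limits.CL - baseline_reference),
        n_beyond_spc=summary.n_beyond_spc,
        n_beyond_action=summary.n_beyond_action,
    )


def analyze_windows(
    series: QASeries,
    specs: list[SpecLimits],
    window_size: int = DEFAULT_WINDOW_SIZE,
    baseline_reference: float = 0.0,
    alpha: float = 0.05,
    action_limit_mm: float = 2.0,
) -> list[WindowReport]:
    """Partition and analyze every window of a long series."""
    return [
        analyze_window(
            ws,
            specs,
            baseline_reference=baseline_reference,
            alpha=alpha,
            action_limit_mm=action_limit_mm,
            window_index=k,
        )
        for k, ws in enumerate(partition_windows(series, window_size))
    ]


def compare_phases(
    before: QASeries,
    after: QASeries,
    specs: list[SpecLimits] | None = None,
    drift_threshold_mm: float = DEFAULT_DRIFT_THRESHOLD_MM,
    alpha: float = 0.05,
    action_limit_mm: float = 2.0,
) -> PhaseComparison:
    """Judge an after phase against limits learned on a before phase.

    verdict is ``systematic_shift`` when |CL_after − CL_before| exceeds
    ``drift_threshold_mm`` or at least :data:`MIN_VIOLATIONS_FOR_SHIFT`
    after-phase points fall outside the before-phase control limits.
    """
    if before.n < MIN_N_FOR_TEST or after.n < MIN_N_FOR_TEST:
        raise InsufficientDataError(
            f"both phases need >= {MIN_N_FOR_TEST} observations, "
            f"got {before.n} and {after.n}"
        )
    if specs is None:
        specs = [SpecLimits.symmetric(2.0)]
    report_a = analyze_window(
        before, specs, alpha=alpha, action_limit_mm=action_limit_mm, window_index=0
    )
    report_b = analyze_window(
        after, specs, alpha=alpha, action_limit_mm=action_limit_mm, window_index=1
    )
    inside = report_a.limits.contains(after.values)
    n_out = int((~inside).sum())
    delta_cl = float(report_b.limits.CL - report_a.limits.CL)
    shift = abs(delta_cl) > drift_threshold_mm or n_out >= MIN_VIOLATIONS_FOR_SHIFT
    return PhaseComparison(
        phase_a=report_a,
        phase_b=report_b,
        delta_CL=delta_cl,
        limits_respected_in_b=(n_out == 0),
        n_b_beyond_a_limits=n_out,
        verdict="systematic_shift" if shift else "stable",
    )
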
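"""Individuals (X) control charts with moving-range control limits.

For a series of single observations x_1..x_n the short-term dispersion is
estimated from the moving range mR_i = |x_i − x_{i−1}|.  The chart lines are

    CL  = mean(x)
    UCL = CL + 3 mR̄ / (d2 √n_sub)
    LCL = CL − 3 mR̄ / (d2 √n_sub)

with n_sub = 1 (individual observations) and d2 the bias constant that maps
the expected range of a subgroup of two normal observations to its standard
deviation: d2(2) = 2/√π ≈ 1.1284 (commonly tabulated as 1.128).  Points
strictly beyond UCL/LCL signal special-cause (systematic) variation; points
beyond a clinical action level (e.g. ±2 mm) are flagged separately — control
limits describe the process, action limits describe the tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

from .errors import InsufficientDataError
from .qa_log_io import QASeries

MOVING_RANGE_SPAN = 2  # consecutive-point window of the moving range


def _values(series) -> np.ndarray:
    """Accept a QASeries or a bare 1-D sequence of offsets."""
    if isinstance(series, QASeries):
        return series.values
    return np.asarray(series, dtype=float)


@dataclass(frozen=True)
class MovingRangeSet:
    """Moving ranges mR_i = |x_i − x_{i−1}| and their mean."""

    mR: np.ndarray
    mR_bar: float
    span: int = MOVING_RANGE_SPAN


@dataclass(frozen=True)
class ControlLimits:
    """Center line and 3-sigma control limits of an individuals chart."""

    CL: float
    UCL: float
    LCL: float
    d2: float
    n_sub: int
    mR_bar: float
    sigma_within: float  # mR̄/d2, the short-term sigma estimate

    def contains(self, x) -> np.ndarray:
        """True where LCL < x < UCL (strict: a point on a limit is in control)."""
        x = np.asarray(x, dtype=float)
        return (x < self.UCL) & (x > self.LCL)


@dataclass(frozen=True)
class PointFlag:
    index: int
    value: float
    beyond_spc: str  # none | above_UCL | below_LCL
    beyond_action: str  # none | above_USL | below_LSL


@dataclass(frozen=True)
class FlagSummary:
    flags: list[PointFlag]
    n_beyond_spc: int
    n_beyond_action: int
    n_in_control: int


@lru_cache(maxsize=None)
def d2_constant(subgroup_size: int) -> float:
    """Expected range of ``subgroup_size`` iid standard normals (the d2 bias
    constant of range-based sigma estimation).

    For subgroups of two the closed form is E|X−Y| = 2/√π; larger subgroups
    use d2(m) = ∫ [1 − Φ(x)^m − (1−Φ(x))^m] dx evaluated numerically.
    """
    if not isinstance(subgroup_size, (int, np.integer)) or not 2 <= subgroup_size <= 10:
        raise ValueError(f"subgroup_size must be an integer in 2..10, got {subgroup_size!r}")
    m = int(subgroup_size)
    if m == 2:
        return 2.0 / np.sqrt(np.pi)

    def integrand(x):
        p = stats.norm.cdf(x)
        return 1.0 - p**m - (1.0 - p) ** m

    value, _ = integrate.quad(integrand, -12, 12, limit=200)
    return float(value)


def moving_ranges(series) -> MovingRangeSet:
    """Moving ranges of consecutive observations; requires n >= 2."""
    x = _values(series)
    if x.size < 2:
        raise InsufficientDataError("moving ranges need at least 2 observations")
    mr = np.abs(np.diff(x))
    return MovingRangeSet(mR=mr, mR_bar=float(mr.mean()))


def chart_limits(series, n_sub: int = 1) -> ControlLimits:
    """Individuals-chart CL/UCL/LCL from the series itself (Phase-I usage).

    A constant series yields UCL = CL = LCL with a warning: the chart is
    degenerate but well defined.
    """
    x = _values(series)
    mrs = moving_ranges(x)
    d2 = d2_constant(MOVING_RANGE_SPAN)
    cl = float(x.mean())
    half_width = 3.0 * mrs.mR_bar / (d2 * np.sqrt(n_sub))
    if mrs.mR_bar == 0.0:
        warnings.warn("constant series: control limits collapse onto the center line")
    return ControlLimits(
        CL=cl,
        UCL=cl + half_width,
        LCL=cl - half_width,
        d2=d2,
        n_sub=n_sub,
        mR_bar=mrs.mR_bar,
        sigma_within=mrs.mR_bar / d2,
    )


def flag_points(series, limits: ControlLimits, action_limit_mm: float = 2.0) -> FlagSummary:
    """Classify every point against control limits and the ±action level.

    Violations use strict inequality: a point exactly on a limit is in
    control.  ``limits`` may come from this series (retrospective use) or
    from an independent baseline run (monitoring use).
    """
    if action_limit_mm <= 0:
        raise ValueError(f"action_limit_mm must be > 0, got {action_limit_mm}")
    x = _values(series)
    flags = []
    n_spc = n_action = 0
    for i, v in enumerate(x):
        if v > limits.UCL:
            spc = "above_UCL"
        elif v < limits.LCL:
            spc = "below_LCL"
        else:
            spc = "none"
        if v > action_limit_mm:
            action = "above_USL"
        elif v < -action_limit_mm:
            action = "below_LSL"
        else:
            action = "none"
        n_spc += spc != "none"
        n_action += action != "none"
        flags.append(PointFlag(index=i, value=float(v), beyond_spc=spc, beyond_action=action))
    return FlagSummary(
        flags=flags,
        n_beyond_spc=n_spc,
        n_beyond_action=n_action,
        n_in_control=len(flags) - n_spc,
    )
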
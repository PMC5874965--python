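"""Applied-vs-detected couch offset analysis.

A known shift is applied on one axis (±0.5, ±1, ±2, ±5 mm) and the onboard
detector reports the offset it sees on all three axes.  This module measures

* per-axis linearity of any recorded response against the applied shift
  (ordinary least squares with R²),
* the worst on-axis detection error (max |detected − applied|) and whether it
  stays inside the clinical tolerance,
* cross-axis coupling: a systematic response on a non-applied axis, the
  signature of the couch's cobra motion (a vertical Z move drags the couch
  longitudinally, coupling Z shifts into the detected Y offset).

Coupling is only declared where it is detectable: applied shifts at or above
``coupling_floor_mm`` whose mean off-axis response exceeds three times the
measurement reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, EmptySelectionError
from .qa_log_io import AXES, OffsetTrial


@dataclass(frozen=True)
class LinearityFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class CouplingReport:
    source_axis: str
    target_axis: str
    magnitude_mm: float  # largest mean |off-axis response| over gated applied values


@dataclass(frozen=True)
class RecoveryVerdict:
    axis: str
    max_abs_deviation_mm: float
    worst_applied_mm: float
    within_action: bool
    coupling_detected: list[CouplingReport]
    deviation_by_applied: dict[float, float]  # mean on-axis deviation per applied value


def fit_linearity(pairs) -> LinearityFit:
    """OLS fit of response vs applied shift; pairs is a sequence of
    (applied_mm, response)."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(np.unique(arr[:, 0])) < 3:
        raise DegenerateDesignError("linearity fit needs >= 3 distinct applied values")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(y) == 0.0:
        # constant response: slope 0, no variance explained
        return LinearityFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, n_points=len(x))
    res = stats.linregress(x, y)
    return LinearityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def _replicate_means(trials: list[OffsetTrial]) -> dict[float, np.ndarray]:
    """Mean detected (x, y, z) per applied value, averaging replicates."""
    out: dict[float, list[np.ndarray]] = {}
    for t in trials:
        out.setdefault(float(t.applied_mm), []).append(np.asarray(t.detected_mm, float))
    return {a: np.mean(v, axis=0) for a, v in out.items()}


def recovery_analysis(
    trials: list[OffsetTrial],
    tolerance_mm: float = 2.0,
    coupling_floor_mm: float = 2.0,
    reproducibility_mm: float = 0.2,
) -> list[RecoveryVerdict]:
    """Per applied-axis verdicts over a whole experiment.

    Replicates are averaged per applied value before comparison.  The on-axis
    deviation at applied value a is mean(detected on that axis) − a; the
    verdict reports the worst one.  Off-axis coupling is reported when the
    mean off-axis response magnitude exceeds 3 × ``reproducibility_mm`` for
    some applied shift with |a| >= ``coupling_floor_mm``.
    """
    if not trials:
        raise EmptySelectionError("no trials supplied")
    verdicts = []
    for axis in AXES:
        axis_trials = [t for t in trials if t.axis == axis]
        if not axis_trials:
            continue
        means = _replicate_means(axis_trials)
        ax_i = AXES.index(axis)
        dev_by_applied = {a: float(m[ax_i] - a) for a, m in means.items()}
        worst_applied = max(dev_by_applied, key=lambda a: abs(dev_by_applied[a]))
        max_dev = abs(dev_by_applied[worst_applied])
        coupling = []
        for tgt_i, tgt in enumerate(AXES):
            if tgt == axis:
                continue
            gated = {
                a: abs(float(m[tgt_i]))
                for a, m in means.items()
                if abs(a) >= coupling_floor_mm
            }
            if gated and max(gated.values()) > 3.0 * reproducibility_mm:
                coupling.append(
                    CouplingReport(
                        source_axis=axis,
                        target_axis=tgt,
                        magnitude_mm=max(gated.values()),
                    )
                )
        verdicts.append(
            RecoveryVerdict(
                axis=axis,
                max_abs_deviation_mm=max_dev,
                worst_applied_mm=float(worst_applied),
                within_action=max_dev <= tolerance_mm,
                coupling_detected=coupling,
                deviation_by_applied=dev_by_applied,
            )
        )
    return verdicts


def cross_axis_matrix(trials: list[OffsetTrial]) -> pd.DataFrame:
    """3×3 response matrix: entry (a, b) is the OLS slope of the detected
    offset on axis b against the shift applied on axis a.  The diagonal of a
    faithful, unbiased system is 1; off-diagonals are coupling slopes."""
    if not trials:
        raise EmptySelectionError("no trials supplied")
    mat = pd.DataFrame(np.nan, index=list(AXES), columns=list(AXES), dtype=float)
    for src in AXES:
        src_trials = [t for t in trials if t.axis == src]
        applied = np.array([t.applied_mm for t in src_trials], dtype=float)
        if len(np.unique(np.abs(applied))) < 2:
            raise DegenerateDesignError(
                f"axis {src}: need >= 2 distinct applied magnitudes, "
                f"got {sorted(set(np.abs(applied)))}"
            )
        for tgt_i, tgt in enumerate(AXES):
            y = np.array([t.detected_mm[tgt_i] for t in src_trials], dtype=float)
            if np.ptp(y) == 0.0:
                mat.loc[src, tgt] = 0.0
            else:
                mat.loc[src, tgt] = float(stats.linregress(applied, y).slope)
    return mat
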
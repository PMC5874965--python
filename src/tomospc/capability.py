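"""Process capability (cp) and acceptability (cpk) against action limits.

    cp  = (USL − LSL) / 6σ
    cpk = min( (USL − X̄)/3σ , (X̄ − LSL)/3σ )

σ is the overall sample standard deviation of the window (the dispersion of
the data distribution), not the within/moving-range estimate — both are
available, but capability uses the overall SD.  cp ≥ 1 means the process
spread fits inside the action band; cpk additionally penalizes an off-center
mean, so cpk = cp exactly when the process sits on the band midpoint and
cpk < cp otherwise.  A window is "acceptable" when both indices are ≥ 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSampleError, InsufficientDataError
from .control_charts import _values

ACCEPTABILITY_THRESHOLD = 1.0


@dataclass(frozen=True)
class SpecLimits:
    """User-specified (clinical action) limits, mm."""

    USL: float
    LSL: float

    def __post_init__(self):
        if not self.USL > self.LSL:
            raise ValueError(f"USL must exceed LSL, got USL={self.USL}, LSL={self.LSL}")

    @classmethod
    def symmetric(cls, half_width_mm: float) -> "SpecLimits":
        return cls(USL=abs(half_width_mm), LSL=-abs(half_width_mm))

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.USL + self.LSL)

    @property
    def width(self) -> float:
        return self.USL - self.LSL


@dataclass(frozen=True)
class CapabilityResult:
    cp: float
    cpk: float
    sigma: float
    mean: float
    spec: SpecLimits
    acceptable: bool
    n: int


def process_sigma(series) -> float:
    """Overall sample standard deviation (n − 1 denominator)."""
    x = _values(series)
    if x.size < 2:
        raise InsufficientDataError("standard deviation needs at least 2 observations")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("constant series: capability is undefined at zero variance")
    return sd


def cp_index(spec: SpecLimits, sigma: float) -> float:
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return spec.width / (6.0 * sigma)


def cpk_index(spec: SpecLimits, mean: float, sigma: float) -> float:
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return min((spec.USL - mean) / (3.0 * sigma), (mean - spec.LSL) / (3.0 * sigma))


def assess_capability(series, spec: SpecLimits) -> CapabilityResult:
    """Combined capability assessment of one analysis window."""
    x = _values(series)
    sigma = process_sigma(x)
    mean = float(x.mean())
    cp = cp_index(spec, sigma)
    cpk = cpk_index(spec, mean, sigma)
    return CapabilityResult(
        cp=cp,
        cpk=cpk,
        sigma=sigma,
        mean=mean,
        spec=spec,
        acceptable=bool(
            cp >= ACCEPTABILITY_THRESHOLD and cpk >= ACCEPTABILITY_THRESHOLD
        ),
        n=int(np.asarray(x).size),
    )
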
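"""Anderson–Darling test of normality with a binary accept/reject decision.

The statistic for an ordered sample X_1 < … < X_n against a hypothesized CDF
F is

    A² = −n − (1/n) Σ_{i=1..n} (2i−1) [ln F(X_i) + ln(1 − F(X_{n+1−i}))]

For the composite null (normal with mean and sd estimated from the sample)
the small-sample modification A²* = A² (1 + 0.75/n + 2.25/n²) is applied and
mapped to a p-value through Stephens' piecewise exponential approximation.
The decision h is 1 (reject normality) when p < alpha, 0 otherwise — the
convention used when charting QA data, where h = 0 certifies the window as
normally distributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, InsufficientDataError
from .qa_log_io import QASeries

#: clamp CDF values away from {0, 1} so the log terms stay finite
_CDF_EPS = 1e-16

#: p-value approximation is unreliable below this sample size
MIN_N_FOR_TEST = 8


@dataclass(frozen=True)
class ADResult:
    A2: float
    A2_star: float
    p_value: float
    alpha: float
    h: int  # 1 = reject normality, 0 = consistent with normal
    n: int
    mean_hat: float
    sd_hat: float


def ad_statistic(sample, distribution_mean: float, distribution_sd: float) -> float:
    """A² against a fully specified normal; the sample need not be sorted."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise InsufficientDataError("A² needs at least 2 observations")
    if distribution_sd <= 0:
        raise ValueError(f"distribution_sd must be > 0, got {distribution_sd}")
    cdf = stats.norm.cdf(x, loc=distribution_mean, scale=distribution_sd)
    cdf = np.clip(cdf, _CDF_EPS, 1.0 - _CDF_EPS)
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(cdf) + np.log(1.0 - cdf[::-1])))
    return float(-n - s / n)


def _stephens_p_value(a2_star: float) -> float:
    """Piecewise exponential p-value for the composite-normal A²* (both
    parameters estimated)."""
    a = a2_star
    if a < 0.2:
        p = 1.0 - np.exp(-13.436 + 101.14 * a - 223.73 * a * a)
    elif a < 0.34:
        p = 1.0 - np.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    elif a < 0.6:
        p = np.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    else:
        p = np.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    return float(min(max(p, 0.0), 1.0))


def ad_test(sample, alpha: float = 0.05) -> ADResult:
    """Composite Anderson–Darling normality test (mean and sd estimated)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < MIN_N_FOR_TEST:
        raise InsufficientDataError(
            f"AD test needs at least {MIN_N_FOR_TEST} observations, got {n}"
        )
    mean_hat = float(x.mean())
    sd_hat = float(x.std(ddof=1))
    if sd_hat == 0.0:
        raise DegenerateSampleError("sample has zero variance; normality test undefined")
    a2 = ad_statistic(x, mean_hat, sd_hat)
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    p = _stephens_p_value(a2_star)
    return ADResult(
        A2=a2,
        A2_star=a2_star,
        p_value=p,
        alpha=alpha,
        h=int(p < alpha),
        n=n,
        mean_hat=mean_hat,
        sd_hat=sd_hat,
    )


def classify_windows_normality(windows, alpha: float = 0.05) -> list[ADResult]:
    """AD test per window, order preserved; errors name the failing window."""
    results = []
    for k, w in enumerate(windows):
        values = w.values if isinstance(w, QASeries) else w
        try:
            results.append(ad_test(values, alpha=alpha))
        except (InsufficientDataError, DegenerateSampleError) as exc:
            raise type(exc)(f"window {k}: {exc}") from exc
    return results
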
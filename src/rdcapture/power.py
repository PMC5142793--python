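"""Trend-detection power analysis (Gerrodette-style).

How many yearly abundance estimates, at what precision, does it take to
detect a population trend by linear regression?  Following Gerrodette
(1987, as amended for small samples), the power of the slope test is
computed analytically: abundance follows the trajectory

    linear:       A_i = A_1 (1 + r t_i),      t_i = 0..n-1,  R = r (n-1)
    exponential:  A_i = A_1 (1 + R)^(t_i/(n-1))

with estimate errors sd_i = CV_i * A_i.  For capture-recapture estimates
the CV is expected to grow with the square root of abundance
(``proportional_to_sqrt_abundance``, the default); constant CV and CV
proportional to 1/sqrt(abundance) are available.  The error variance is
pooled along the trajectory and the one-tailed slope t-test's power is
the upper tail of a noncentral t with n-2 degrees of freedom.

``min_detectable_change`` inverts power over the overall change by
bisection; ``min_detectable_decline_percent`` reads the threshold off an
integer-percent grid with power compared at the two-decimal precision at
which power tables are conventionally reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

CV_RELATIONS = (
    "constant",
    "proportional_to_sqrt_abundance",
    "inverse_sqrt_abundance",
)


@dataclass(frozen=True)
class PowerSettings:
    """Conventions of the power analysis.

    alpha
        Type-I error probability of the slope test.
    tails
        1 (trend direction specified in advance) or 2.
    change_type
        'linear' or 'exponential' trajectory of abundance.
    cv_abundance_relation
        How the CV of an estimate scales with abundance along the
        trajectory; the supplied CV is anchored at the first estimate.
    power_target
        Power level at which thresholds are inverted (default 0.8).
    """

    alpha: float = 0.05
    tails: int = 1
    change_type: str = "linear"
    cv_abundance_relation: str = "proportional_to_sqrt_abundance"
    power_target: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError("power_target must be in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.change_type not in ("linear", "exponential"):
            raise ValueError("change_type must be linear or exponential")
        if self.cv_abundance_relation not in CV_RELATIONS:
            raise ValueError(f"cv_abundance_relation must be one of {CV_RELATIONS}")


def trajectory(n_samples: int, overall_change: float, change_type: str) -> np.ndarray:
    """Relative abundance A_i / A_1 over i = 0..n-1."""
    t = np.arange(n_samples, dtype=float)
    if change_type == "linear":
        return 1.0 + overall_change * t / (n_samples - 1)
    return (1.0 + overall_change) ** (t / (n_samples - 1))


def trend_power(
    n_samples: int,
    cv: float,
    overall_change: float,
    settings: PowerSettings = PowerSettings(),
) -> float:
    """Power of the regression slope test for a given overall change.

    ``overall_change`` is the signed fractional change over the whole
    series (-0.47 = an overall 47% decline).  Power at zero change
    equals alpha by construction.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to test a slope")
    if cv <= 0:
        raise ValueError("cv must be positive")
    if overall_change <= -1.0:
        raise ValueError("a decline cannot exceed 100%")
    A = trajectory(n_samples, overall_change, settings.change_type)
    if settings.cv_abundance_relation == "constant":
        cvs = np.full(n_samples, cv)
    elif settings.cv_abundance_relation == "proportional_to_sqrt_abundance":
        cvs = cv * np.sqrt(A / A[0])
    else:
        cvs = cv * np.sqrt(A[0] / A)
    sd = cvs * A
    t = np.arange(n_samples, dtype=float)
    s_tt = float(np.sum((t - t.mean()) ** 2))
    sigma2 = float(np.mean(sd**2))  # pooled error variance along the trajectory
    slope = (A[-1] - A[0]) / (n_samples - 1)
    ncp = abs(slope) / math.sqrt(sigma2 / s_tt)
    df = n_samples - 2
    alpha = settings.alpha if settings.tails == 1 else settings.alpha / 2.0
    t_crit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(t_crit, df, ncp))


def min_detectable_change(
    n_samples: int,
    cv: float,
    settings: PowerSettings = PowerSettings(),
    tol: float = 1e-4,
) -> float:
    """Smallest overall decline (fraction) detectable at the target power.

    Bisection on the overall change; returns ``nan`` ("not detectable")
    if even a near-complete decline does not reach the target.
    """
    hi = 0.9999
    if trend_power(n_samples, cv, -hi, settings) < settings.power_target:
        return float("nan")
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if trend_power(n_samples, cv, -mid, settings) >= settings.power_target:
            hi = mid
        else:
            lo = mid
    return hi


def min_detectable_decline_percent(
    n_samples: int,
    cv: float,
    settings: PowerSettings = PowerSettings(),
    power_decimals: int = 2,
) -> int:
    """Minimum detectable overall decline on the integer-percent grid.

    Steps through whole-percent declines and returns the first whose
    power, at the ``power_decimals`` precision of a printed power table,
    reaches the target.  This is the reporting convention of published
    trend-power tables (a power of 0.7989 prints as 0.80).
    """
    for pct in range(1, 100):
        p = round(trend_power(n_samples, cv, -pct / 100.0, settings), power_decimals)
        if p >= settings.power_target:
            return pct
    raise ValueError("no detectable decline below 100%")


def samples_required(
    cv: float,
    overall_change: float,
    settings: PowerSettings = PowerSettings(),
    max_samples: int = 200,
) -> int:
    """Smallest number of yearly samples whose power reaches the target."""
    for n in range(3, max_samples + 1):
        if trend_power(n, cv, overall_change, settings) >= settings.power_target:
            return n
    raise ValueError(f"target power not reached within {max_samples} samples")


def power_profile(
    cv: float,
    overall_change: float,
    max_samples: int,
    settings: PowerSettings = PowerSettings(),
):
    """Power as a function of series length (the numeric content of a
    power-vs-duration figure); returns a list of (n, power)."""
    return [
        (n, trend_power(n, cv, overall_change, settings))
        for n in range(3, max_samples + 1)
    ]
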
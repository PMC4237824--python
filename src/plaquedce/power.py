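"""Sample-size planning from a scan-rescan coefficient of variation.

Treatment-effect detection is framed on percent change (follow-up minus
baseline, normalized by the baseline mean) compared between two arms with a
two-sided unpaired t-test. Assuming measurement error is the dominant
within-arm variability, the per-arm SD of percent change is the
single-measurement between-scan CV multiplied by sqrt(2) (the change is a
difference of two measurements). The required n per arm solves the
noncentral-t power equation

    power(n) = P(|T| > t_{1-alpha/2, 2n-2}),
    T ~ noncentral t(df = 2n-2, nc = delta / (sigma * sqrt(2/n)))

over continuous n (degrees of freedom 2n - 2), the solution then rounded
to the nearest integer — the behaviour of R's ``power.t.test`` followed by
rounding, which this module reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerSpec",
    "cv_of_change",
    "power_two_sample_t",
    "solve_n_continuous",
    "sample_size_per_arm",
    "sample_size_curve",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs: single-measurement CV, detectable percent difference
    (both as fractions of the baseline mean), target power and two-sided
    alpha."""

    cv_single: float
    pct_diff: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.cv_single <= 0:
            raise ValueError("cv_single must be positive")
        if not 0 < self.pct_diff < 2:
            raise ValueError("pct_diff must be in (0, 2)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def cv_of_change(cv_single: float) -> float:
    """CV of the change score: single-measurement CV times sqrt(2)."""
    if cv_single <= 0:
        raise ValueError("cv_single must be positive")
    return cv_single * math.sqrt(2.0)


def power_two_sample_t(n: float, delta: float, sigma: float,
                       alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at ``n`` per arm.

    ``n`` may be non-integer (df = 2n - 2 continuous); the noncentral t
    distribution is used exactly, no normal shortcut.
    """
    if n <= 1:
        return 0.0
    df = 2.0 * n - 2.0
    nc = delta / (sigma * math.sqrt(2.0 / n))
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))


def solve_n_continuous(delta: float, sigma: float, power: float = 0.80,
                       alpha: float = 0.05, max_n: float = 1e7) -> float:
    """Continuous n per arm at which the noncentral-t power equals ``power``."""
    # bracket from n = 2 (the smallest design a two-sample t-test admits;
    # the noncentral t degenerates as df -> 0)
    f = lambda n: power_two_sample_t(n, delta, sigma, alpha) - power
    lo = 2.0
    if f(lo) >= 0:
        return lo
    if f(max_n) < 0:
        raise OverflowError(
            f"required sample size exceeds the cap of {max_n:g} per arm")
    hi = 4.0
    while f(hi) < 0:
        hi = min(hi * 2.0, max_n)
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def sample_size_per_arm(spec: PowerSpec, max_n: float = 1e7) -> int:
    """Subjects per arm to detect ``pct_diff`` given the single-measurement CV.

    Solves the continuous noncentral-t power equation with
    sigma = cv_single * sqrt(2) and rounds to the nearest integer
    (round half up).
    """
    sigma = cv_of_change(spec.cv_single)
    n = solve_n_continuous(spec.pct_diff, sigma, spec.power, spec.alpha, max_n)
    return int(math.floor(n + 0.5))


def sample_size_curve(cv_single: float, diffs, power: float = 0.80,
                      alpha: float = 0.05, label: str = "") -> pd.DataFrame:
    """Sample-size table over a grid of detectable differences.

    Returns a DataFrame with columns (parameter, pct_diff, n_per_arm),
    non-increasing in pct_diff.
    """
    diffs = np.atleast_1d(np.asarray(diffs, dtype=float))
    if diffs.size == 0:
        raise ValueError("diffs must be non-empty")
    rows = [{"parameter": label, "pct_diff": float(d),
             "n_per_arm": sample_size_per_arm(
                 PowerSpec(cv_single=cv_single, pct_diff=float(d),
                           power=power, alpha=alpha))}
            for d in diffs]
    return pd.DataFrame(rows)
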
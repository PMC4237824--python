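"""Scan-rescan reproducibility statistics for paired cohort tables.

A cohort table is a pandas DataFrame with one row per subject and columns
``subject_id, vendor, y1, y2, area1, area2`` (complete cases: both scans
present). The measurement model is the balanced random-intercept model

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2)

whose variance components are estimated by the one-way random-effects
ANOVA moment estimator, which coincides with REML in this balanced
two-scan design (up to truncation of a negative between-subject variance
at zero). From the components follow the between-scan SD sigma_w, the
between-scan CV = sigma_w / mu, and the ICC =
sigma_b^2 / (sigma_b^2 + sigma_w^2); 95% confidence intervals come from a
subject-level nonparametric percentile bootstrap (scan pairs resampled
intact). Vendor differences in means are tested with the mixed model
(reducing, in the balanced case, to a two-sample t-test on subject means)
and differences in between-scan SDs with a permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORT_COLUMNS",
    "validate_cohort",
    "VarianceComponents",
    "ReproducibilityResult",
    "PairedTResult",
    "VendorComparison",
    "paired_t_test",
    "fit_variance_components",
    "cv_between_scan",
    "icc",
    "bootstrap_ci",
    "reproducibility",
    "vendor_compare",
    "per_subject_sd",
    "spearman",
    "bland_altman",
    "subgroup_by_area",
]

COHORT_COLUMNS = ("subject_id", "vendor", "y1", "y2", "area1", "area2")


class SchemaError(ValueError):
    """A table does not match the declared cohort schema."""


def validate_cohort(table: pd.DataFrame, require_areas: bool = False) -> pd.DataFrame:
    required = ["subject_id", "vendor", "y1", "y2"]
    if require_areas:
        required += ["area1", "area2"]
    for col in required:
        if col not in table.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    if table["subject_id"].duplicated().any():
        raise SchemaError("cohort table must have one row per subject")
    if table[["y1", "y2"]].isna().any().any():
        raise SchemaError("cohort table must be complete-case (no missing scans)")
    return table


@dataclass(frozen=True)
class VarianceComponents:
    """Random-intercept model estimates: grand mean, between-subject SD,
    between-scan SD. ``truncated`` records a negative between-subject
    variance estimate clipped to zero."""

    grand_mean: float
    sigma_b: float
    sigma_w: float
    truncated: bool = False


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean1: float
    mean2: float
    degenerate: bool = False


@dataclass(frozen=True)
class ReproducibilityResult:
    """Point estimates and bootstrap 95% CIs of the reproducibility metrics."""

    components: VarianceComponents
    cv: float
    icc: float
    ci_sd: tuple[float, float]
    ci_cv: tuple[float, float]
    ci_icc: tuple[float, float]
    n_subjects: int


@dataclass(frozen=True)
class VendorComparison:
    p_mean: float
    p_sd: float
    sd_ge: float
    sd_philips: float
    n_ge: int
    n_philips: int


# --------------------------------------------------------------------------
# core estimators

def paired_t_test(table: pd.DataFrame) -> PairedTResult:
    """Two-sided paired t-test of scan 1 vs scan 2 means."""
    validate_cohort(table)
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    y1 = table["y1"].to_numpy(float)
    y2 = table["y2"].to_numpy(float)
    d = y1 - y2
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTResult(t=0.0, p=1.0, mean1=float(y1.mean()),
                                 mean2=float(y2.mean()), degenerate=True)
        # constant nonzero shift: t diverges, p has limit 0; flagged degenerate
        return PairedTResult(t=math.inf if d.mean() > 0 else -math.inf,
                             p=0.0, mean1=float(y1.mean()),
                             mean2=float(y2.mean()), degenerate=True)
    res = stats.ttest_rel(y1, y2)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue),
                         mean1=float(y1.mean()), mean2=float(y2.mean()))


def _components_from_arrays(y1: np.ndarray, y2: np.ndarray):
    """Vectorized balanced one-way ANOVA components.

    ``y1``/``y2`` may carry leading replicate axes; subjects are the last
    axis. Returns (mu, sigma_b, sigma_w, truncated) arrays.
    """
    n = y1.shape[-1]
    mu = (y1.mean(axis=-1) + y2.mean(axis=-1)) / 2.0
    d = y1 - y2
    msw = np.mean(d * d / 2.0, axis=-1)
    subj_mean = (y1 + y2) / 2.0
    msb = 2.0 * np.sum((subj_mean - mu[..., None]) ** 2, axis=-1) / (n - 1)
    var_b = (msb - msw) / 2.0
    truncated = var_b < 0
    var_b = np.maximum(var_b, 0.0)
    return mu, np.sqrt(var_b), np.sqrt(msw), truncated


def fit_variance_components(table: pd.DataFrame) -> VarianceComponents:
    """Balanced one-way random-effects ANOVA estimator of (mu, sigma_b, sigma_w).

    sigma_w^2 = MSW (mean of d_i^2 / 2 over subjects),
    sigma_b^2 = max(0, (MSB - MSW) / 2), mu = grand mean. Equivalent to REML
    for this balanced two-scan design whenever the between-subject variance
    estimate is non-negative.
    """
    validate_cohort(table)
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    mu, sb, sw, trunc = _components_from_arrays(
        table["y1"].to_numpy(float), table["y2"].to_numpy(float))
    return VarianceComponents(grand_mean=float(mu), sigma_b=float(sb),
                              sigma_w=float(sw), truncated=bool(trunc))


def cv_between_scan(components: VarianceComponents) -> float:
    """Between-scan coefficient of variation: sigma_w / grand mean."""
    if components.grand_mean <= 0:
        raise ValueError("CV undefined for non-positive grand mean")
    return components.sigma_w / components.grand_mean


def icc(components: VarianceComponents) -> float:
    """Intra-class correlation sigma_b^2 / (sigma_b^2 + sigma_w^2).

    All-constant data (both components zero) maps to 0 by convention: there
    is no between-subject variance for the measurement to resolve.
    """
    tot = components.sigma_b ** 2 + components.sigma_w ** 2
    if tot == 0.0:
        return 0.0
    return components.sigma_b ** 2 / tot


# --------------------------------------------------------------------------
# bootstrap

_STATISTICS = ("sd", "cv", "icc")


def _bootstrap_values(y1, y2, statistic: str, B: int, rng) -> np.ndarray:
    n = y1.size
    idx = rng.integers(0, n, size=(B, n))
    b1, b2 = y1[idx], y2[idx]
    mu, sb, sw, _ = _components_from_arrays(b1, b2)
    if statistic == "sd":
        return sw
    if statistic == "cv":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(mu > 0, sw / mu, np.nan)
        return out
    if statistic == "icc":
        tot = sb ** 2 + sw ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(tot > 0, sb ** 2 / tot, 0.0)
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {_STATISTICS}")


def bootstrap_ci(table: pd.DataFrame, statistic: str, B: int = 2000,
                 seed: int = 0, levels: tuple[float, float] = (2.5, 97.5)):
    """Subject-level nonparametric percentile bootstrap interval.

    Subjects are resampled with replacement with their scan pairs kept
    intact; the statistic ("sd", "cv" or "icc") is recomputed per replicate
    and the percentile interval returned as ``(lo, hi, unstable)`` where
    ``unstable`` flags the statistic being undefined in > 10% of replicates.
    """
    validate_cohort(table)
    if B < 200:
        raise ValueError("B must be at least 200")
    if len(table) < 5:
        raise ValueError("need at least 5 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    vals = _bootstrap_values(table["y1"].to_numpy(float),
                             table["y2"].to_numpy(float), statistic, B, rng)
    bad = ~np.isfinite(vals)
    unstable = bad.mean() > 0.10
    vals = vals[~bad]
    lo, hi = np.percentile(vals, levels)
    return float(lo), float(hi), bool(unstable)


def reproducibility(table: pd.DataFrame, B: int = 2000,
                    seed: int = 0) -> ReproducibilityResult:
    """Full reproducibility summary: components, CV, ICC and bootstrap CIs."""
    comp = fit_variance_components(table)
    return ReproducibilityResult(
        components=comp,
        cv=cv_between_scan(comp),
        icc=icc(comp),
        ci_sd=bootstrap_ci(table, "sd", B, seed)[:2],
        ci_cv=bootstrap_ci(table, "cv", B, seed + 1)[:2],
        ci_icc=bootstrap_ci(table, "icc", B, seed + 2)[:2],
        n_subjects=len(table),
    )


# --------------------------------------------------------------------------
# vendor comparison

def vendor_compare(table: pd.DataFrame, n_perm: int = 10000,
                   seed: int = 0) -> VendorComparison:
    """Test vendor differences in means and in between-scan SDs.

    ``p_mean``: balanced mixed-model comparison of vendor means, which for
    this design reduces to a two-sample t-test on the subject means.
    ``p_sd``: permutation test on |sigma_w(GE) - sigma_w(Philips)| with
    vendor labels permuted across subjects,
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    validate_cohort(table)
    ge = table[table["vendor"] == "GE"]
    ph = table[table["vendor"] == "Philips"]
    if len(ge) < 3 or len(ph) < 3:
        raise ValueError("need at least 3 subjects per vendor")
    sm_ge = (ge["y1"].to_numpy(float) + ge["y2"].to_numpy(float)) / 2.0
    sm_ph = (ph["y1"].to_numpy(float) + ph["y2"].to_numpy(float)) / 2.0
    p_mean = float(stats.ttest_ind(sm_ge, sm_ph).pvalue)

    # half squared scan differences: their group mean is sigma_w^2
    h = ((table["y1"] - table["y2"]).to_numpy(float)) ** 2 / 2.0
    n, n_ge = len(table), len(ge)
    is_ge = (table["vendor"] == "GE").to_numpy()
    sd_ge = math.sqrt(h[is_ge].mean())
    sd_ph = math.sqrt(h[~is_ge].mean())
    observed = abs(sd_ge - sd_ph)

    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_ge]
    perm_ge = h[perm].mean(axis=1)
    perm_ph = (h.sum() - h[perm].sum(axis=1)) / (n - n_ge)
    perm_stat = np.abs(np.sqrt(perm_ge) - np.sqrt(perm_ph))
    p_sd = (1.0 + np.sum(perm_stat >= observed - 1e-15)) / (n_perm + 1.0)
    return VendorComparison(p_mean=p_mean, p_sd=float(p_sd),
                            sd_ge=sd_ge, sd_philips=sd_ph,
                            n_ge=n_ge, n_philips=n - n_ge)


# --------------------------------------------------------------------------
# per-subject variability and association

def per_subject_sd(table: pd.DataFrame) -> pd.Series:
    """Per-subject between-scan SD: |y1 - y2| / sqrt(2) (two-point sample SD)."""
    validate_cohort(table)
    d = (table["y1"] - table["y2"]).abs() / math.sqrt(2.0)
    return pd.Series(d.to_numpy(float), index=table["subject_id"].to_numpy(),
                     name="between_scan_sd")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided
    t-approximation p-value. Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need two equal-length samples with n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bland_altman(table: pd.DataFrame) -> tuple[float, float, float]:
    """Bland-Altman summary of the scan differences d_i = y2 - y1.

    Returns (mean difference, lower limit, upper limit) with limits of
    agreement at mean(d) +/- 2 * SD(d) — factor 2, the convention used for
    the scan-rescan agreement plots this mirrors.
    """
    validate_cohort(table)
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    d = (table["y2"] - table["y1"]).to_numpy(float)
    m = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return m, m - 2.0 * sd, m + 2.0 * sd


def subgroup_by_area(table: pd.DataFrame, min_area: float = 25.0) -> pd.DataFrame:
    """Restrict to subjects whose smaller-of-two-scans analyzed plaque area
    is at least ``min_area`` mm^2 (the large-lesion subgroup)."""
    validate_cohort(table, require_areas=True)
    keep = np.minimum(table["area1"].to_numpy(float),
                      table["area2"].to_numpy(float)) >= min_area
    return table.loc[keep].reset_index(drop=True)
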
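"""Method-comparison statistics for validating gait estimates.

Implements the agreement toolkit used to compare an estimation method
against reference measurements: percentage Bland-Altman (per-pair difference
as a percentage of the pair mean, with 95% limits of agreement),
Passing-Bablok regression (nonparametric slope/intercept robust to error in
both variables), Lin's concordance correlation coefficient, and median
absolute error / median absolute percent error with interquartile ranges.
Quantiles use linear interpolation (type 7) so reported medians and IQRs are
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PairedSeries:
    """Reference (ground-truth) and estimated values for one metric."""

    reference: np.ndarray
    estimate: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.reference, dtype=float)
        e = np.asarray(self.estimate, dtype=float)
        if r.shape != e.shape or r.ndim != 1:
            raise ValueError("reference and estimate must be 1-D arrays of equal length")
        if len(r) < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(e))):
            raise ValueError("paired series must be finite")
        object.__setattr__(self, "reference", r)
        object.__setattr__(self, "estimate", e)

    @property
    def n(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_pct_diff: float
    ci: tuple
    loa: tuple
    sd_pct_diff: float
    n: int


def bland_altman_percent(p: PairedSeries) -> BlandAltmanResult:
    """Percentage Bland-Altman: per-pair difference normalized by the pair mean.

    %diff_i = 100 * (estimate_i - reference_i) / ((estimate_i + reference_i)/2);
    positive bias means overestimation.  The mean %diff carries a
    normal-theory 95% CI (sd/sqrt(n)); limits of agreement are
    mean +/- 1.96 sd.
    """
    means = (p.estimate + p.reference) / 2.0
    zero = np.flatnonzero(means == 0.0)
    if len(zero):
        raise ValueError(f"pair mean of 0 at index {int(zero[0])}; percentage difference undefined")
    pct = 100.0 * (p.estimate - p.reference) / means
    mean = float(np.mean(pct))
    sd = float(np.std(pct, ddof=1)) if p.n > 1 else 0.0
    half = _Z95 * sd / math.sqrt(p.n)
    return BlandAltmanResult(
        mean_pct_diff=mean,
        ci=(mean - half, mean + half),
        loa=(mean - 1.96 * sd, mean + 1.96 * sd),
        sd_pct_diff=sd,
        n=p.n,
    )


@dataclass(frozen=True)
class PassingBablokResult:
    slope: float
    slope_ci: tuple
    intercept: float
    intercept_ci: tuple
    n: int


def _shifted_median(sorted_slopes: np.ndarray, k: int) -> float:
    n = len(sorted_slopes)
    # 1-based median position, shifted by K (the count of slopes < -1)
    if n % 2:
        return float(sorted_slopes[(n + 1) // 2 + k - 1])
    lo = sorted_slopes[n // 2 + k - 1]
    hi = sorted_slopes[n // 2 + k]
    return float((lo + hi) / 2.0)


def passing_bablok(p: PairedSeries) -> PassingBablokResult:
    """Passing-Bablok regression of estimate on reference.

    All pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i) for i < j are
    enumerated; pairs with equal x and equal y are excluded, equal-x pairs
    with differing y contribute signed infinities, and slopes equal to -1
    are dropped.  The slope is the median of the sorted slopes shifted by
    K = #{S_ij < -1}, which makes the estimator invariant to swapping the
    axes; the intercept is median(y_i - slope * x_i).  CIs use the
    large-sample rank normal approximation.
    """
    x, y = p.reference, p.estimate
    n = p.n
    if n < 4:
        raise ValueError("Passing-Bablok needs at least 4 pairs")
    if np.all(x == x[0]):
        raise ValueError("all reference values identical; slope undefined")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    slopes = np.empty(len(dx))
    nz = dx != 0
    slopes[nz] = dy[nz] / dx[nz]
    slopes[~nz] = np.sign(dy[~nz]) * np.inf  # equal-x pairs with differing y
    slopes = slopes[slopes != -1.0]
    if len(slopes) == 0:
        raise ValueError("no valid pairwise slopes")
    slopes = np.sort(slopes)
    big_n = len(slopes)
    k = int(np.sum(slopes < -1.0))
    b = _shifted_median(slopes, k)

    # rank-based normal-approximation CI
    w = _Z95 * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    m1 = max(1, m1 + k)
    m2 = min(big_n, m2 + k)
    b_lo, b_hi = float(slopes[m1 - 1]), float(slopes[m2 - 1])

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return PassingBablokResult(slope=b, slope_ci=(b_lo, b_hi), intercept=a, intercept_ci=(a_lo, a_hi), n=n)


def lins_ccc(p: PairedSeries) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2).
    """
    x, y = p.reference, p.estimate
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    denom = sx2 + sy2 + float((x.mean() - y.mean()) ** 2)
    if denom == 0.0:
        raise ValueError("both series constant with equal means; concordance undefined")
    return 2.0 * sxy / denom


@dataclass(frozen=True)
class MedianErrorResult:
    mdae: float
    mdae_iqr: tuple
    mdape: float
    mdape_iqr: tuple
    n_excluded: int


def median_errors(p: PairedSeries) -> MedianErrorResult:
    """Median absolute error and median absolute percent error with IQRs.

    Pairs with a zero reference are excluded from MdAPE (count logged);
    quantiles use linear interpolation.
    """
    err = np.abs(p.estimate - p.reference)
    mdae = float(np.median(err))
    mdae_iqr = (float(np.percentile(err, 25)), float(np.percentile(err, 75)))
    nz = p.reference != 0.0
    n_excl = int(np.sum(~nz))
    if n_excl:
        logger.warning("median_errors: excluding %d zero-reference pairs from MdAPE", n_excl)
    if not np.any(nz):
        raise ValueError("all reference values are zero; MdAPE undefined")
    ape = 100.0 * err[nz] / np.abs(p.reference[nz])
    mdape = float(np.median(ape))
    mdape_iqr = (float(np.percentile(ape, 25)), float(np.percentile(ape, 75)))
    return MedianErrorResult(mdae=mdae, mdae_iqr=mdae_iqr, mdape=mdape, mdape_iqr=mdape_iqr, n_excluded=n_excl)


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics for one metric's paired comparison."""

    label: str
    n: int
    bland_altman: BlandAltmanResult
    passing_bablok: PassingBablokResult
    ccc: float
    median_error: MedianErrorResult


def agreement_report(p: PairedSeries) -> AgreementReport:
    """Compute the full agreement panel for a paired comparison."""
    return AgreementReport(
        label=p.label,
        n=p.n,
        bland_altman=bland_altman_percent(p),
        passing_bablok=passing_bablok(p),
        ccc=lins_ccc(p),
        median_error=median_errors(p),
    )


def acceptance_flags(report: AgreementReport, max_reference: float) -> dict:
    """Agreement flags against the standard acceptance bands.

    Strong slope agreement: the Passing-Bablok slope CI contains 1;
    acceptable: slope within [0.9, 1.1].  Intercept acceptable when within
    2% of the maximum reference value.  Concordance: strong > 0.95,
    acceptable > 0.9.
    """
    pb = report.passing_bablok
    return {
        "slope_strong": pb.slope_ci[0] <= 1.0 <= pb.slope_ci[1],
        "slope_acceptable": 0.9 <= pb.slope <= 1.1,
        "intercept_acceptable": abs(pb.intercept) <= 0.02 * max_reference,
        "ccc_strong": report.ccc > 0.95,
        "ccc_acceptable": report.ccc > 0.9,
    }
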
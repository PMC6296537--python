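"""Observer-agreement statistics: Bland-Altman, ICC, kappa, Spearman.

These mirror the reproducibility analyses used to validate the image
analysis against repeated readings: Bland-Altman bias and 95% limits of
agreement (mean difference +/- 1.96 SD of the paired differences, with the
mean relative difference expressed against the grand mean of both
observers), absolute-agreement two-way single-measures ICC(A,1) with its
F-based confidence interval, unweighted Cohen's kappa for the binary
red/white classification, and Spearman rank correlation for continuous
parameters against the six-stage grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError

__all__ = [
    "BlandAltmanResult",
    "IccResult",
    "KappaResult",
    "bland_altman",
    "icc_absolute_agreement",
    "cohen_kappa",
    "spearman",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_relative_diff_pct: float


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way mixed, absolute agreement, single measures (ICC A,1)"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman comparison of two paired series.

    Differences are ``x - y``; sd uses the n-1 denominator; the relative
    difference is 100 * mean_diff / grand mean of all pooled values.
    Requires length >= 2.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be 1-D series of equal length")
    if x.size < 2:
        raise AnalysisError("bland_altman needs at least 2 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AnalysisError("missing values are not allowed")
    d = x - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    grand_mean = float(np.mean(np.concatenate([x, y])))
    rel = math.nan if grand_mean == 0 else 100.0 * mean_diff / grand_mean
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - _Z95 * sd_diff,
        loa_high=mean_diff + _Z95 * sd_diff,
        mean_relative_diff_pct=rel,
    )


def icc_absolute_agreement(ratings, alpha: float = 0.05) -> IccResult:
    """ICC(A,1): two-way model, absolute agreement, single measures.

    ``ratings`` is a complete subjects x raters matrix (>= 2 of each). The
    estimate follows the mean-squares form of McGraw & Wong, with the
    F-based 95% CI. Zero total variance yields NaN (undefined).
    """
    r = np.asarray(ratings, dtype=np.float64)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise AnalysisError("ratings must be a subjects x raters matrix, >= 2 each")
    if not np.isfinite(r).all():
        raise AnalysisError("ratings matrix must be complete")
    n, k = r.shape
    grand = r.mean()
    if np.allclose(r, grand):
        return IccResult(icc=math.nan, ci_low=math.nan, ci_high=math.nan)

    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)  # subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # raters
    sse = np.sum((r - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    # F-based interval (Satterthwaite df for the rater+error composite)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    if not (math.isfinite(a) and math.isfinite(b)) or (a * msc + b * mse) == 0:
        return IccResult(icc=float(icc), ci_low=math.nan, ci_high=math.nan)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_star = stats.f.ppf(1 - alpha / 2, v, n - 1)
    f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
    ci_low = n * (msr - f_lower * mse) / (
        f_lower * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_star * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_star * msr)
    return IccResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high))


def cohen_kappa(a, b) -> KappaResult:
    """Unweighted Cohen's kappa between two categorical series.

    po is the raw agreement fraction, pe the chance agreement from the
    marginal products; kappa = (po - pe) / (1 - pe), NaN when pe = 1.
    """
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise AnalysisError("series lengths differ")
    if not a:
        raise AnalysisError("empty series")
    n = len(a)
    categories = sorted({str(x) for x in a} | {str(x) for x in b})
    a = [str(x) for x in a]
    b = [str(x) for x in b]
    po = sum(x == y for x, y in zip(a, b)) / n
    pe = sum((a.count(c) / n) * (b.count(c) / n) for c in categories)
    kappa = math.nan if pe == 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(kappa=kappa, observed_agreement=po, expected_agreement=pe)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with t-approximation p-value.

    Returns (rho, p); (NaN, NaN) when either series has zero rank variance.
    Requires length >= 3.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise AnalysisError("spearman needs paired 1-D series of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
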
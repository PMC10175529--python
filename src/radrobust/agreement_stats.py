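"""Agreement and dispersion statistics for feature robustness.

Implements, from their defining formulas: Bland–Altman test–retest
analysis with 1.96·SD limits of agreement, the coefficient of variation
(CV) and quartile coefficient of dispersion (QCD), the intraclass
correlation ICC(A,1) (two-way random effects, absolute agreement,
single rater), Lin's concordance correlation coefficient (CCC), and
Spearman rank correlation.

Sign/variant conventions used throughout the package:

* Bland–Altman differences are rescan − scan.
* CV uses the absolute mean in the denominator so negative-valued
  features do not yield negative CVs; QCD likewise uses |Q3 + Q1|.
* Near-zero denominators are flagged degenerate and mapped to the +inf
  sentinel, which fails every "< cutoff" classification rather than
  dropping the feature.
* Quartiles are linear interpolation of order statistics (position
  p·(n−1)+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltmanResult",
    "DispersionValue",
    "AgreementValue",
    "bland_altman",
    "cv",
    "qcd",
    "dispersion",
    "icc_a1",
    "ccc",
    "spearman",
]

LOA_MULTIPLIER = 1.96  # classical Bland–Altman limits, not a t quantile
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    frac_within: float
    repeatable: bool
    p_bias: float
    n: int


@dataclass(frozen=True)
class DispersionValue:
    cv_pct: float
    qcd_pct: float
    n: int
    degenerate_flag: bool


@dataclass(frozen=True)
class AgreementValue:
    icc: float
    ccc: float
    n_subjects: int
    degenerate_flag: bool


def bland_altman(scan: np.ndarray, rescan: np.ndarray,
                 cutoff: float = 0.90) -> BlandAltmanResult:
    """Bland–Altman repeatability of paired scan/rescan measurements.

    ``repeatable`` is true when the fraction of differences lying within
    bias ± 1.96·SD reaches ``cutoff`` (default: 90% of the pairs).  A
    zero SD means all differences are identical; by convention every
    point is then within the (collapsed) limits.  ``p_bias`` is the
    two-sided one-sample t test of the differences against zero.
    """
    x = np.asarray(scan, float)
    y = np.asarray(rescan, float)
    if x.shape != y.shape:
        raise ValueError("scan and rescan must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = bias - LOA_MULTIPLIER * sd
    hi = bias + LOA_MULTIPLIER * sd
    if sd == 0.0:
        frac = 1.0
        p = 1.0 if bias == 0.0 else 0.0
    else:
        frac = float(((d >= lo) & (d <= hi)).mean())
        t = bias / (sd / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return BlandAltmanResult(bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
                             frac_within=frac, repeatable=frac >= cutoff,
                             p_bias=p, n=n)


def cv(values: np.ndarray) -> float:
    """Coefficient of variation in percent: 100·SD(n−1)/|mean|.

    Returns +inf (degenerate) when the mean is negligible relative to
    the SD; constant input gives exactly 0.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("cv needs at least 2 values")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return 0.0
    m = abs(float(x.mean()))
    if m < _DEGENERATE_TOL * sd:
        return math.inf
    return 100.0 * sd / m


def qcd(values: np.ndarray) -> float:
    """Quartile coefficient of dispersion in percent: 100·(Q3−Q1)/|Q3+Q1|."""
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("qcd needs at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    iqr = float(q3 - q1)
    if iqr == 0.0:
        return 0.0
    s = abs(float(q3 + q1))
    if s < _DEGENERATE_TOL * iqr:
        return math.inf
    return 100.0 * iqr / s


def dispersion(values: np.ndarray) -> DispersionValue:
    """CV and QCD of one feature across platforms, with degeneracy flag.

    QCD needs at least 4 values; with fewer it is reported as NaN
    (undefined) instead of raising, so small studies still yield CVs.
    """
    c = cv(values)
    q = qcd(values) if len(values) >= 4 else math.nan
    return DispersionValue(cv_pct=c, qcd_pct=q, n=len(values),
                           degenerate_flag=not (math.isfinite(c) and math.isfinite(q)))


def icc_a1(data: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``data`` is an (n_subjects × k_raters) matrix.  From the two-way
    ANOVA mean squares MSR (subjects), MSC (raters) and MSE (residual):

        ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    A matrix with zero total variance returns 1 (perfect, degenerate).
    """
    X = np.asarray(data, float)
    if X.ndim != 2:
        raise ValueError("data must be a 2D subjects × raters matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need n_subjects >= 3 and k_raters >= 2")
    if not np.isfinite(X).all():
        raise ValueError("incomplete matrix: non-finite entries")
    grand = X.mean()
    sst = float(((X - grand) ** 2).sum())
    if sst <= _DEGENERATE_TOL * max(1.0, grand ** 2) * X.size:
        return 1.0
    rm = X.mean(axis=1)
    cm = X.mean(axis=0)
    ssr = k * float(((rm - grand) ** 2).sum())
    ssc = n * float(((cm - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return 1.0
    return float((msr - mse) / denom)


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

        CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

    Two constant, equal vectors give 1; constant vectors with different
    means give 0.
    """
    a = np.asarray(x, float)
    b = np.asarray(y, float)
    if a.shape != b.shape:
        raise ValueError("x and y must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    ma, mb = a.mean(), b.mean()
    va = float(((a - ma) ** 2).mean())
    vb = float(((b - mb) ** 2).mean())
    cov = float(((a - ma) * (b - mb)).mean())
    denom = va + vb + (ma - mb) ** 2
    if denom == 0.0:
        return 1.0
    return float(2.0 * cov / denom)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Spearman rank correlation: (rho, rho², two-sided p).

    Average ranks for ties; rho is the Pearson correlation of the ranks;
    the p value uses the t approximation with n−2 degrees of freedom.
    """
    a = np.asarray(x, float)
    b = np.asarray(y, float)
    if a.shape != b.shape:
        raise ValueError("x and y must have equal length")
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    r2 = rho * rho
    if r2 >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - r2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, r2, p
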
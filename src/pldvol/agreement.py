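"""Agreement and reliability statistics for method-comparison studies.

Implements, from their defining formulas, the statistics used to validate
a new volumetry method against a reference and between assessors:

* ICC(2,1) — two-way random-effects, single-measure, absolute-agreement
  intraclass correlation with its F-based 95% confidence interval
  (Shrout & Fleiss 1979; McGraw & Wong 1996).
* Bland–Altman limits of agreement — mean difference ± 1.96 SD of the
  paired differences.
* Spearman's rank correlation — Pearson correlation of average ranks,
  with the two-sided t-approximation p-value.
* Cohort change-rate summary — mean with a Student-t 95% CI.

These are deliberately authored here (scipy supplies only distribution
quantiles and ranking); library implementations serve as cross-checks in
the test suite, not as the computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "icc_2_1",
    "bland_altman",
    "spearman_rho",
    "cohort_change_summary",
    "LOA_MULTIPLIER",
]

#: Fixed multiplier for the 95% limits of agreement (not recomputed from n).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """ICC point estimate with 95% CI and the ANOVA mean squares behind it."""

    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement between two paired series (first − second)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray  # per-pair means, for plotting
    diffs: np.ndarray  # per-pair differences, for plotting


def _as_ratings(values, drop_missing: bool) -> np.ndarray:
    arr = np.asarray(getattr(values, "values", values), dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"ratings must be an n×k matrix, got shape {arr.shape}")
    if drop_missing:
        keep = ~np.isnan(arr).any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d subject(s) with missing ratings", dropped)
        arr = arr[keep]
    elif np.isnan(arr).any():
        raise ValueError("ratings contain missing values")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got n={n}, k={k}")
    return arr


def icc_2_1(values, *, drop_missing: bool = True, alpha: float = 0.05) -> AgreementResult:
    """ICC(2,1): two-way random-effects, absolute-agreement, single measure.

    The two-way ANOVA decomposes the n×k ratings into subject (rows),
    rater (columns) and residual mean squares, and

        ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)).

    The 95% CI uses the F-based interval with Satterthwaite degrees of
    freedom. Absolute agreement penalizes systematic rater offsets, unlike
    the consistency variant. Negative estimates are reported as computed.

    Parameters
    ----------
    values : array-like or DataFrame, shape (n subjects, k raters)
        Subjects with any missing rating are dropped (logged) when
        ``drop_missing`` is true.
    """
    arr = _as_ratings(values, drop_missing)
    n, k = arr.shape

    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    # the subtraction leaves float residue when the additive model is exact
    if ss_err < 1e-12 * max(ss_total, 1e-300):
        ss_err = 0.0

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    scale = max(abs(arr).max(), 1.0)
    if ss_total <= (1e-12 * scale) ** 2 * n * k:
        logger.warning("zero total variance: ICC defined as 1 with degenerate CI")
        return AgreementResult(1.0, 1.0, 1.0, msr, msc, mse, n, k)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom
    if icc < 0:
        logger.warning("negative ICC estimate (%.4f): less agreement than chance", icc)

    if mse <= 0:
        # perfect within-cell reproduction; the F interval is degenerate
        return AgreementResult(icc, icc, icc, msr, msc, mse, n, k)

    # F-based CI with Satterthwaite df (McGraw & Wong 1996, case 2A single)
    fc = msc / mse
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    if math.isinf(a):
        return AgreementResult(icc, icc, icc, msr, msc, mse, n, k)
    vn = (k - 1) * (n - 1) * (k * icc * fc + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fc**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    with np.errstate(invalid="ignore", over="ignore"):
        lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    if not math.isfinite(lo):
        lo = icc
    if not math.isfinite(hi):
        hi = icc
    lo, hi = min(lo, icc), max(hi, icc)
    return AgreementResult(icc, lo, hi, msr, msc, mse, n, k)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement of two paired series.

    Differences are oriented first − second; the 95% limits of agreement
    are mean ± 1.96 SD (sample SD, n−1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d incomplete pair(s)", dropped)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    diffs = x - y
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        n=n,
        means=(x + y) / 2.0,
        diffs=diffs,
    )


def spearman_rho(x, y) -> tuple:
    """Spearman's rank correlation with a two-sided t-approximation p-value.

    Ties get average ranks; rho is the Pearson correlation of the rank
    vectors and p comes from t = rho·√((n−2)/(1−rho²)) on n−2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant series")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, p


def cohort_change_summary(rates, *, alpha: float = 0.05) -> tuple:
    """Mean change rate (%) with a Student-t confidence interval.

    Returns ``(mean, (ci_low, ci_high))`` where the CI is
    mean ± t_{1−α/2, n−1} · sd/√n.
    """
    r = np.asarray(rates, dtype=float)
    r = r[~np.isnan(r)]
    n = r.size
    if n < 2:
        raise ValueError(f"need at least 2 rates, got {n}")
    mean = float(r.mean())
    half = float(stats.t.ppf(1 - alpha / 2, n - 1)) * float(r.std(ddof=1)) / math.sqrt(n)
    return mean, (mean - half, mean + half)
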
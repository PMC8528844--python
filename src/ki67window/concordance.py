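"""Method-agreement statistics for two Ki67 readouts.

Used to compare the automated index against a reference reading (visual
counts, or the generator's ground truth): Spearman rank correlation with an
exact small-sample permutation p, the two-way random-effects absolute-
agreement intraclass correlation ICC(2,1) with its F-based confidence
interval, and simple label-agreement accuracy for nucleus positivity calls.

ICC(2,1) is the standard choice for single-rater absolute agreement in
method-comparison studies; the consistency form ICC(3,1) is also exposed
because the two differ exactly when the readers disagree by a systematic
offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedScores",
    "SpearmanResult",
    "ICCResult",
    "AccuracyResult",
    "spearman",
    "icc",
    "classification_accuracy",
]

_EXACT_SPEARMAN_MAX_N = 8


@dataclass
class PairedScores:
    """Two readers' scores on the same samples, pairwise-complete."""

    sample_ids: list
    reader_a: np.ndarray
    reader_b: np.ndarray

    @classmethod
    def from_arrays(cls, a, b, sample_ids=None) -> "PairedScores":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("reader vectors must be equal-length 1-d arrays")
        if sample_ids is None:
            sample_ids = list(range(len(a)))
        keep = ~(np.isnan(a) | np.isnan(b))
        if keep.sum() < 3:
            raise ValueError("need at least 3 complete pairs")
        return cls(
            sample_ids=[s for s, k in zip(sample_ids, keep) if k],
            reader_a=a[keep],
            reader_b=b[keep],
        )

    @property
    def n(self) -> int:
        return len(self.reader_a)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str
    degenerate: bool = False


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    icc_consistency: float
    confidence: float
    n: int
    degenerate: bool = False


@dataclass
class AccuracyResult:
    accuracy: float
    n: int
    per_class: dict


def _rank_rho(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    return float((ra * rb).sum() / denom)


def spearman(
    paired: PairedScores, alternative: str = "two-sided"
) -> SpearmanResult:
    """Spearman rho with average-tie ranks.

    p exact by exhaustive permutation for n <= 8, else the usual
    t-approximation.  Constant input is flagged degenerate (rho undefined).
    """
    a, b = paired.reader_a, paired.reader_b
    n = paired.n
    if np.all(a == a[0]) or np.all(b == b[0]):
        return SpearmanResult(np.nan, np.nan, n, "degenerate", degenerate=True)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = _rank_rho(ra, rb)
    if n <= _EXACT_SPEARMAN_MAX_N:
        null = np.array(
            [_rank_rho(ra, rb[list(perm)]) for perm in itertools.permutations(range(n))]
        )
        tol = 1e-12
        if alternative == "two-sided":
            p = float((np.abs(null) >= abs(rho) - tol).mean())
        elif alternative == "greater":
            p = float((null >= rho - tol).mean())
        elif alternative == "less":
            p = float((null <= rho + tol).mean())
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return SpearmanResult(rho, p, n, "exact-permutation")
    res = stats.spearmanr(a, b, alternative=alternative)
    return SpearmanResult(float(res.statistic), float(res.pvalue), n, "t-approximation")


def icc(paired: PairedScores, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way mean-squares decomposition; the CI uses the
    standard F-based interval and the p-value tests ICC = 0 via
    F = MSR / MSE on ((n-1), (n-1)(k-1)) df.
    """
    if paired.n < 5:
        raise ValueError("ICC requires at least 5 paired samples")
    y = np.stack([paired.reader_a, paired.reader_b], axis=1)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    sse = sst - ssr - ssc
    dfr, dfc, dfe = n - 1, k - 1, (n - 1) * (k - 1)
    msr, msc, mse = ssr / dfr, ssc / dfc, sse / dfe
    if msr <= 0 or np.isclose(ssr, 0.0):
        return ICCResult(
            np.nan, np.nan, np.nan, np.nan, np.nan, confidence, n, degenerate=True
        )
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc3 = (msr - mse) / (msr + (k - 1) * mse)

    alpha = 1.0 - confidence
    if mse > 0:
        fj = msc / mse
        vn = dfe * (k * icc2 * fj + n * (1 + (k - 1) * icc2) - k * icc2) ** 2
        vd = dfr * k**2 * icc2**2 * fj**2 + (
            n * (1 + (k - 1) * icc2) - k * icc2
        ) ** 2
        v = vn / vd
        f1 = stats.f.ppf(1 - alpha / 2, dfr, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, dfr)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
        p = float(stats.f.sf(msr / mse, dfr, dfe))
    else:
        lower = upper = 1.0
        p = 0.0
    return ICCResult(
        icc=float(icc2),
        ci_low=float(lower),
        ci_high=float(upper),
        p_value=p,
        icc_consistency=float(icc3),
        confidence=confidence,
        n=n,
    )


def classification_accuracy(predicted, true) -> AccuracyResult:
    """Fraction of label agreements plus per-class sensitivity/specificity."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape or predicted.ndim != 1 or len(true) < 1:
        raise ValueError("label vectors must be equal-length, non-empty, 1-d")
    acc = float((predicted == true).mean())
    per_class = {}
    for cls in np.unique(true):
        is_cls = true == cls
        sens = float((predicted[is_cls] == cls).mean())
        spec = (
            float((predicted[~is_cls] != cls).mean()) if (~is_cls).any() else np.nan
        )
        per_class[str(cls)] = {"sensitivity": sens, "specificity": spec}
    return AccuracyResult(accuracy=acc, n=len(true), per_class=per_class)
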
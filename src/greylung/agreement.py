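"""Agreement and comparison statistics.

Spearman rank correlation with a seeded bootstrap confidence interval and the
strength classes used throughout (strong >= 0.70, moderate >= 0.50, fair
>= 0.30, weak < 0.30, on |rho|); Friedman's test across pressure steps with
post-hoc Wilcoxon signed-rank pairs under Bonferroni correction; and the
two-way random-effects intraclass correlation ICC(2,1) — single rater,
absolute agreement — for interobserver variability, computed from the
two-way ANOVA mean squares with an F-distribution confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "CorrelationResult",
    "ICCResult",
    "PairwiseComparison",
    "spearman",
    "classify_strength",
    "friedman",
    "wilcoxon_pairs",
    "icc_two_way_random",
]

STRENGTH_THRESHOLDS = (("strong", 0.70), ("moderate", 0.50), ("fair", 0.30))
ALPHA = 0.05  # study-wide significance threshold


def classify_strength(rho: float) -> str:
    """Strength class of a correlation coefficient, on |rho| with closed
    lower bounds: >= 0.70 strong, >= 0.50 moderate, >= 0.30 fair, else weak."""
    if not -1 <= rho <= 1:
        raise ValidationError("rho must lie in [-1, 1]")
    r = abs(rho)
    for label, bound in STRENGTH_THRESHOLDS:
        if r >= bound:
            return label
    return "weak"


@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    strength: str


def spearman(x, y, ci_method: str = "bootstrap", n_boot: int = 2000,
             seed: int = 0, alpha: float = ALPHA) -> CorrelationResult:
    """Spearman's rho with average ranks for ties.

    The p-value comes from the t approximation. The confidence interval is a
    seeded percentile bootstrap by default (distribution-free, appropriate
    for the skewed greyscale data the statistic is used on); ``ci_method=
    "fisher"`` switches to the Fisher-z interval with the Fieller-Hartley-
    Pearson variance 1.06/(n-3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValidationError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant variable")

    res = stats.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        rhos = np.empty(n_boot)
        for b in range(n_boot):
            xb, yb = x[idx[b]], y[idx[b]]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                rhos[b] = np.nan
                continue
            rhos[b] = stats.spearmanr(xb, yb).statistic
        lo, hi = np.nanpercentile(rhos, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    elif ci_method == "fisher":
        z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
        se = np.sqrt(1.06 / (n - 3))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    return CorrelationResult(rho=rho, ci_low=float(lo), ci_high=float(hi),
                             p_value=p, n=n, strength=classify_strength(rho))


def friedman(block_matrix) -> tuple[float, float]:
    """Friedman chi-square over a complete subjects x conditions block.

    Average ranks within each subject row, with the standard tie correction;
    p from the chi-square distribution on k-1 degrees of freedom. A matrix
    whose rows are all fully tied (e.g. identical columns) gives statistic 0
    and p = 1.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2:
        raise ValidationError("block_matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if k < 2 or n < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")
    if np.isnan(m).any():
        raise ValidationError("complete blocks required (missing cells found)")

    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum((col_sums - n * (k + 1) / 2) ** 2)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (n * k * (k ** 2 - 1))
    if correction <= 0:
        return 0.0, 1.0
    stat /= correction
    return float(stat), float(stats.chi2.sf(stat, k - 1))


@dataclass
class PairwiseComparison:
    pair: tuple
    n: int
    statistic: float
    raw_p: float
    adjusted_p: float
    significant: bool
    degenerate: bool = False


def wilcoxon_pairs(block_matrix, pairs: Sequence[tuple[int, int]],
                   m_comparisons: int | None = None,
                   alpha: float = ALPHA) -> list[PairwiseComparison]:
    """Post-hoc paired Wilcoxon signed-rank tests with Bonferroni correction.

    ``block_matrix`` is subjects x conditions; each pair names two condition
    columns. Zero differences are dropped; the exact null distribution is
    used for n <= 25 informative pairs, a normal approximation beyond. The
    Bonferroni family size defaults to the number of pairs tested;
    adjusted_p = min(1, raw_p * m). A pair whose differences are all zero is
    flagged degenerate (raw_p = 1, never significant).
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2:
        raise ValidationError("block_matrix must be 2-D")
    k = m.shape[1]
    for i, j in pairs:
        if not (0 <= i < k and 0 <= j < k):
            raise ValidationError(f"pair ({i}, {j}) outside the condition columns")
    m_family = m_comparisons if m_comparisons is not None else len(pairs)

    out = []
    for i, j in pairs:
        diffs = m[:, i] - m[:, j]
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            out.append(PairwiseComparison(pair=(i, j), n=0, statistic=np.nan,
                                          raw_p=1.0, adjusted_p=1.0,
                                          significant=False, degenerate=True))
            continue
        method = "exact" if nonzero.size <= 25 else "approx"
        try:
            res = stats.wilcoxon(nonzero, zero_method="wilcox", method=method)
        except ValueError:  # ties can defeat the exact method
            res = stats.wilcoxon(nonzero, zero_method="wilcox", method="approx")
        raw_p = float(res.pvalue)
        adj = min(1.0, raw_p * m_family)
        out.append(PairwiseComparison(pair=(i, j), n=int(nonzero.size),
                                      statistic=float(res.statistic),
                                      raw_p=raw_p, adjusted_p=adj,
                                      significant=adj < alpha))
    return out


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model_label: str
    n_subjects: int
    n_raters: int


ICC_LABEL = "ICC(2,1): two-way random effects, absolute agreement, single rater"


def icc_two_way_random(ratings, alpha: float = ALPHA) -> ICCResult:
    """ICC(2,1) from the two-way ANOVA mean squares.

    ``ratings`` is subjects x raters, complete. The estimate is
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n); the confidence
    interval follows the F-distribution method of McGraw & Wong with
    Satterthwaite degrees of freedom. Identical rater columns give exactly 1
    with a degenerate interval.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValidationError("ratings must be 2-D (subjects x raters)")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValidationError("need >= 5 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise ValidationError("complete ratings required")

    grand = m.mean()
    if np.ptp(m) == 0:
        raise ValidationError("ICC undefined for constant ratings")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValidationError("ICC undefined: zero variance decomposition")
    icc = (msr - mse) / denom

    tol = 1e-12 * msr  # roundoff floor for the rater variance components
    if mse <= tol and msc <= tol:  # perfect duplicate columns
        return ICCResult(1.0, 1.0, 1.0, ICC_LABEL, n, k)

    # McGraw & Wong F-based interval for ICC(A,1)
    fc = msc / mse
    num_v = (k - 1) * (n - 1) * (k * icc * fc + n * (1 + (k - 1) * icc)
                                 - k * icc) ** 2
    den_v = ((n - 1) * k ** 2 * icc ** 2 * fc ** 2
             + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = num_v / den_v
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = (n * (msr - f_lo * mse)
              / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
    ci_high = (n * (f_hi * msr - mse)
               / (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
    return ICCResult(float(icc), float(ci_low), float(ci_high),
                     ICC_LABEL, n, k)
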
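"""Reproducibility and association statistics for morphometric fibrosis.

This module implements the statistics used to validate a quantitative
fibrosis readout against repeated measurements and ordinal Banff grading:

* one-way random-effects single-rater intraclass correlation, ICC(1,1),
  with its F-distribution-based 95% confidence interval — the standard
  agreement measure when each biopsy is scored by raters regarded as
  interchangeable;
* Fisher-z confidence intervals for Pearson correlations, including the
  "from printed estimate" variants that reconstruct an interval from a
  published point estimate and sample size alone;
* paired location tests (Wilcoxon signed-rank and paired t);
* simple ordinary least squares with the slope t-test;
* per-group summaries and the seeded simulators used to exercise all of
  the above.

ICC(1,1) background: with n subjects each rated k times, the one-way
ANOVA decomposition gives between-subject and within-subject mean squares
MSB and MSW.  The estimator is

    ICC = (MSB - MSW) / (MSB + (k - 1) * MSW)

and, because F = MSB/MSW follows an F(n-1, n(k-1)) distribution scaled by
(1 + k*rho/(1-rho)), confidence bounds follow by pivoting:

    F_L = F / F_{1-a/2}(n-1, n(k-1)),   F_U = F * F_{1-a/2}(n(k-1), n-1)
    rho_bound = (F_bound - 1) / (F_bound + k - 1).

The same pivot applied to an ICC *point estimate* (inverting it to its
implied F) reconstructs the interval without raw data, which is how
published intervals can be checked from the printed estimate and n alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, PreconditionError, UndefinedStatisticError


@dataclass
class PairedRatings:
    """An n x k table of repeated ratings (k raters or repeats)."""

    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise PreconditionError("ratings must be a 2-D (n x k) table")
        if len(self.subject_ids) != self.values.shape[0]:
            raise PreconditionError("one subject id per row required")
        if np.isnan(self.values).any():
            raise PreconditionError(
                "missing cells are not allowed; drop incomplete subjects upstream"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n: int
    k: int
    alpha: float = 0.05
    model: str = "oneway_random_single"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate, "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper, "f_stat": self.f_stat,
            "df1": self.df1, "df2": self.df2, "p_value": self.p_value,
            "n": self.n, "k": self.k, "alpha": self.alpha, "model": self.model,
        }


@dataclass
class CorrelationResult:
    r: float
    ci_lower: float
    ci_upper: float
    n: int
    p_value: float
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "r": self.r, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "n": self.n, "p_value": self.p_value, "alpha": self.alpha,
        }


@dataclass
class RegressionResult:
    intercept: float
    slope: float
    r_squared: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept, "slope": self.slope,
            "r_squared": self.r_squared, "p_value": self.p_value, "n": self.n,
        }


@dataclass
class GroupSpec:
    """Summary of one ordinal-grade group: label, n, mean, sample SD."""

    label: int
    n: int
    mean: float
    sd: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise PreconditionError("group n must be >= 1")
        if self.sd < 0:
            raise PreconditionError("group sd must be >= 0")
        if self.sd == 0:
            self.degenerate = True


@dataclass
class PairedTestResult:
    p_wilcoxon: float
    p_paired_t: float
    n: int
    degenerate: bool = False


def _icc_ci_from_f(
    f: float, n: int, k: int, alpha: float
) -> tuple[float, float]:
    df1, df2 = n - 1, n * (k - 1)
    f_l = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1.0) / (f_l + k - 1.0)
    hi = (f_u - 1.0) / (f_u + k - 1.0)
    return float(lo), float(hi)


def icc_oneway(ratings: PairedRatings, alpha: float = 0.05) -> ICCResult:
    """One-way random-effects single-rater ICC(1,1) with F-based 95% CI.

    Raises :class:`UndefinedStatisticError` when the table has zero total
    variance (every cell identical), where the ICC is undefined.
    """
    n, k = ratings.n, ratings.k
    if n < 3:
        raise PreconditionError("ICC requires at least 3 subjects")
    if k < 2:
        raise PreconditionError("ICC requires at least 2 ratings per subject")
    x = ratings.values
    grand = x.mean()
    if np.allclose(x, grand):
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((x - row_means[:, None]) ** 2)
    df1, df2 = n - 1, n * (k - 1)
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0.0:
        # perfect within-subject agreement
        return ICCResult(
            estimate=1.0, ci_lower=1.0, ci_upper=1.0, f_stat=np.inf,
            df1=df1, df2=df2, p_value=0.0, n=n, k=k, alpha=alpha,
        )
    f = msb / msw
    estimate = (msb - msw) / (msb + (k - 1) * msw)
    lo, hi = _icc_ci_from_f(f, n, k, alpha)
    p = float(stats.f.sf(f, df1, df2))
    return ICCResult(
        estimate=float(estimate), ci_lower=lo, ci_upper=hi, f_stat=float(f),
        df1=df1, df2=df2, p_value=p, n=n, k=k, alpha=alpha,
    )


def icc_ci_from_estimate(
    icc: float, n: int, k: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Reconstruct the F-based CI of ICC(1,1) from its point estimate.

    Inverts the estimate to its implied variance-ratio statistic
    ``F = (1 + (k-1) icc) / (1 - icc)`` and applies the same F pivot as
    :func:`icc_oneway`, so the pair of functions agree exactly on any
    dataset.  Useful for checking published intervals where only the
    estimate and sample size are printed.
    """
    if n < 3:
        raise PreconditionError("need n >= 3")
    if k < 2:
        raise PreconditionError("need k >= 2")
    if icc >= 1.0:
        if icc == 1.0:
            return 1.0, 1.0
        raise PreconditionError("icc must be <= 1")
    if icc <= -1.0 / (k - 1):
        raise PreconditionError(f"icc must exceed {-1.0 / (k - 1):.3f} for k={k}")
    f = (1.0 + (k - 1) * icc) / (1.0 - icc)
    return _icc_ci_from_f(f, n, k, alpha)


def pearson_ci_from_estimate(
    r: float, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Fisher-z confidence interval from a correlation point estimate.

    ``tanh(atanh(r) +/- z_{1-a/2} / sqrt(n - 3))``; degenerate (collapsed)
    at |r| = 1.
    """
    if n < 4:
        raise PreconditionError("Fisher-z CI requires n >= 4")
    if abs(r) > 1:
        raise PreconditionError("|r| must be <= 1")
    if abs(r) == 1.0:
        return float(r), float(r)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Pearson r with Fisher-z CI and two-sided t-test p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise PreconditionError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 4:
        raise PreconditionError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    lo, hi = pearson_ci_from_estimate(r, n, alpha)
    return CorrelationResult(
        r=r, ci_lower=lo, ci_upper=hi, n=n, p_value=float(res.pvalue),
        alpha=alpha,
    )


def simulate_paired_ratings(
    true_icc: float, n: int, k: int, seed: int
) -> PairedRatings:
    """Draw an n x k table with the requested population ICC(1,1).

    ``value[i, j] = s_i + e_ij`` with subject effects of variance
    ``true_icc`` and residuals of variance ``1 - true_icc``, so total
    variance is 1 and the intraclass correlation is exactly ``true_icc``.
    """
    if not 0.0 <= true_icc < 1.0:
        raise ParameterError("true_icc must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, np.sqrt(true_icc), size=n)
    resid = rng.normal(0.0, np.sqrt(1.0 - true_icc), size=(n, k))
    return PairedRatings(
        subject_ids=[f"S{i}" for i in range(n)],
        values=subj[:, None] + resid,
    )


def simulate_grouped(
    groups: Sequence[GroupSpec], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw normal samples per group summary; returns (values, labels)."""
    if len(groups) == 0:
        raise PreconditionError("need at least one group")
    rng = np.random.default_rng(seed)
    values, labels = [], []
    for g in groups:
        values.append(rng.normal(g.mean, g.sd, size=g.n))
        labels.append(np.full(g.n, g.label))
    return np.concatenate(values), np.concatenate(labels)


def paired_location_test(
    before: Sequence[float], after: Sequence[float]
) -> PairedTestResult:
    """Wilcoxon signed-rank and paired t test, two-sided.

    Wilcoxon uses the exact null distribution when the number of non-zero
    differences is at most 25, and the normal approximation with
    continuity correction above that; zero differences are dropped
    (Wilcoxon convention).  All-zero differences return p = 1 with the
    degenerate flag set.
    """
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    if before.shape != after.shape or before.ndim != 1:
        raise PreconditionError("before/after must be equal-length 1-D sequences")
    diff = after - before
    nz = diff[diff != 0]
    if len(nz) == 0:
        return PairedTestResult(
            p_wilcoxon=1.0, p_paired_t=1.0, n=len(diff), degenerate=True
        )
    if len(nz) < 5:
        raise PreconditionError(
            "need at least 5 non-zero differences for the signed-rank test"
        )
    method = "exact" if len(nz) <= 25 else "approx"
    w = stats.wilcoxon(
        diff, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    t = stats.ttest_rel(after, before)
    return PairedTestResult(
        p_wilcoxon=float(w.pvalue), p_paired_t=float(t.pvalue), n=len(diff)
    )


def ols_simple(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple least-squares line with slope t-test and R^2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise PreconditionError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise PreconditionError("need n >= 3")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("x is constant; fit undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def group_summary(
    values: Sequence[float], labels: Sequence[int]
) -> list[GroupSpec]:
    """Per-label n, mean and sample SD (ddof=1), labels ascending.

    Single-observation groups get sd = 0 and the degenerate flag.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise PreconditionError("values and labels must align")
    specs = []
    for lab in np.unique(labels):
        v = values[labels == lab]
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        specs.append(
            GroupSpec(label=int(lab), n=len(v), mean=float(v.mean()), sd=sd)
        )
    return specs
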
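"""Reliability and comparison statistics for measurement studies.

Implements the single-measure absolute-agreement intraclass correlation
ICC(A,1) of McGraw & Wong (1996) with its F-based 95% CI, Bland–Altman 95%
limits of agreement (1.96·SD multiplier), paired and Welch t-tests, and exact
noncentral-t power / sample size for the paired t-test.  Difference-based
quantities are always oriented first-argument − second-argument and carry an
explicit orientation tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

LOA_MULTIPLIER = 1.96

__all__ = [
    "RaterTable",
    "ICCResult",
    "BlandAltmanResult",
    "PairedTestResult",
    "PowerSpec",
    "icc_absolute_single",
    "icc_category",
    "bland_altman",
    "limits_of_agreement",
    "paired_t",
    "welch_t",
    "power_paired_t",
    "sample_size_paired_t",
]


@dataclass
class RaterTable:
    """Complete n×k matrix of one measurement made by k raters on n subjects."""

    values: np.ndarray
    subject_ids: list[str] | None = None
    rater_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rater table must be a 2D subjects × raters matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n}×{k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rater table contains missing or non-finite cells")
        if self.subject_ids is None:
            self.subject_ids = [f"S{i + 1}" for i in range(n)]
        if self.rater_labels is None:
            self.rater_labels = [f"rater_{j + 1}" for j in range(k)]
        if len(self.subject_ids) != n or len(self.rater_labels) != k:
            raise ValueError("id/label lengths do not match the matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    msr: float  # between-subject (rows) mean square
    msc: float  # between-rater (columns) mean square
    mse: float  # residual mean square
    n: int
    k: int
    category: str


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    orientation: str = "first - second"
    coordinates: np.ndarray | None = None  # (pair mean, pair diff) per pair


@dataclass
class PairedTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    sd_diff: float | None
    ci_low: float
    ci_high: float
    variant: str  # "paired" | "welch-unpaired"
    orientation: str = "first - second"


@dataclass
class PowerSpec:
    """Design parameters for a paired t-test power/sample-size computation.

    ``effect_size`` is Cohen's d on the paired differences (mean/SD of the
    within-pair difference).
    """

    effect_size: float
    alpha: float = 0.05
    tails: int = 2

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect size must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_category(icc: float) -> str:
    """Reliability label: <0.50 poor, 0.50–0.75 moderate, 0.76–0.90 good, >0.90 excellent."""
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def icc_absolute_single(table: RaterTable, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC from a two-way ANOVA decomposition.

    Point estimate (McGraw & Wong ICC(A,1)):

        (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    with the standard F-based confidence interval.  The two-way mixed vs
    random distinction does not change the point estimate.
    """
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = float(((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum())
    if ssr + ssc + sse <= 0:
        raise ValueError("degenerate table: no variance in any direction")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if msc == 0.0 and mse == 0.0:
        # perfect agreement: the interval degenerates with the estimate
        lo = hi = 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            with np.errstate(invalid="ignore", divide="ignore"):
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
                f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f_low * mse) / (
                    f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
                hi = n * (f_up * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f_up * msr)
            # estimates at the boundary can make the F interval collapse
            if not np.isfinite(lo):
                lo = icc
            if not np.isfinite(hi):
                hi = icc
        else:
            lo = hi = 1.0
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     msr=msr, msc=msc, mse=mse, n=n, k=k,
                     category=icc_category(float(icc)))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def limits_of_agreement(mean_diff: float, sd_diff: float) -> tuple[float, float]:
    """95% limits of agreement from a printed mean ± SD of paired differences."""
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    half = LOA_MULTIPLIER * sd_diff
    return mean_diff - half, mean_diff + half


def bland_altman(first, second) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements (diff = first − second)."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1D measurement arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("measurements must be finite")
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    lo, hi = limits_of_agreement(mean_diff, sd_diff)
    coords = np.column_stack(((a + b) / 2.0, diff))
    return BlandAltmanResult(mean_diff=mean_diff, sd_diff=sd_diff,
                             loa_low=lo, loa_high=hi, n=a.size,
                             coordinates=coords)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def paired_t(first, second, alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired t-test on within-pair differences (first − second)."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length arrays of >= 2 pairs")
    diff = a - b
    n = diff.size
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("degenerate: constant nonzero difference has no "
                             "paired-t sampling variance")
    else:
        t_stat = mean / (sd / np.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    half = float(sps.t.ppf(1 - alpha / 2, df)) * (sd / np.sqrt(n))
    return PairedTestResult(t=float(t_stat), df=df, p=p, mean_diff=mean,
                            sd_diff=sd, ci_low=mean - half, ci_high=mean + half,
                            variant="paired")


def welch_t(group_a, group_b, alpha: float = 0.05) -> PairedTestResult:
    """Unequal-variance two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        raise ValueError("degenerate: both groups have zero variance")
    se2 = va / na + vb / nb
    mean = float(a.mean() - b.mean())
    t_stat = mean / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    half = float(sps.t.ppf(1 - alpha / 2, df)) * np.sqrt(se2)
    return PairedTestResult(t=float(t_stat), df=float(df), p=p, mean_diff=mean,
                            sd_diff=None, ci_low=mean - half, ci_high=mean + half,
                            variant="welch-unpaired")


# ---------------------------------------------------------------------------
# power / sample size (exact noncentral t)
# ---------------------------------------------------------------------------

def power_paired_t(spec: PowerSpec, n: int) -> float:
    """Exact power of the paired t-test with n pairs at the spec's d, alpha, tails.

    The test statistic follows a noncentral t with df = n−1 and noncentrality
    d·√n under the alternative; power integrates its tails beyond the central-t
    critical value.
    """
    if n < 2:
        raise ValueError("need at least 2 pairs")
    df = n - 1
    ncp = spec.effect_size * np.sqrt(n)
    if spec.tails == 2:
        t_crit = sps.t.ppf(1 - spec.alpha / 2, df)
        return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))
    t_crit = sps.t.ppf(1 - spec.alpha, df)
    return float(sps.nct.sf(t_crit, df, ncp))


def sample_size_paired_t(spec: PowerSpec, target_power: float) -> int:
    """Smallest n with power_paired_t(spec, n) >= target_power."""
    if not 0 < target_power < 1:
        raise ValueError("target power must lie in (0, 1)")
    # bracket by doubling, then binary search on the monotone power curve
    lo, hi = 2, 4
    while power_paired_t(spec, hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10 ** 8:
            raise RuntimeError("sample size search failed to terminate")
    if power_paired_t(spec, lo) >= target_power:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_paired_t(spec, mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
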
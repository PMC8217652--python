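"""Bootstrap t-tests, Bonferroni correction, effect sizes and permutation tests.

Conventions:

* paired comparisons report the classical paired t statistic and a
  t-distribution 95% CI of the mean difference, plus a two-sided bootstrap
  p-value from percentile resampling of the paired differences;
* the paired effect size is ``d = |t| / sqrt(n)``;
* independent comparisons use the Welch t statistic, group-wise bootstrap
  resampling, and a pooled-SD standardized mean difference;
* the permutation test uses the difference of group means with add-one
  smoothing, ``p = (#{|perm| >= |obs|} + 1) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateGroups, LengthMismatch, TooFewPairs, TooFewValues


@dataclass(frozen=True)
class PairedTestResult:
    mean_a: float
    mean_b: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    d: float
    n: int


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p: float
    n_perm: int
    d: float
    seed: int | None


def cohens_d_paired(t: float, n: int) -> float:
    """Paired effect size ``|t| / sqrt(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return abs(t) / np.sqrt(n)


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled standard deviation of two independent samples (ddof=1)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(var))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison threshold ``alpha / m`` (0.05 / 7 prints as 0.007)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def ci_from_t(mean_diff: float, t: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Reconstruct the CI of a mean difference from its t statistic.

    Uses ``SE = |mean_diff| / |t|`` and the t quantile with ``df = n - 1``,
    so printed (mean, t) pairs can be checked against printed CI bounds.
    """
    if t == 0:
        raise ValueError("cannot reconstruct a CI from t = 0")
    se = abs(mean_diff) / abs(t)
    q = sps.t.ppf(0.5 + level / 2.0, df=n - 1)
    return mean_diff - q * se, mean_diff + q * se


def _two_sided_percentile_p(boot_stats: np.ndarray) -> float:
    """Two-sided bootstrap p: is 0 in the tails of the resampled statistic?

    ``p = 2 * min(P(stat* <= 0), P(stat* >= 0))`` capped at 1; degenerate
    all-zero distributions give p = 1.
    """
    lo = np.mean(boot_stats <= 0)
    hi = np.mean(boot_stats >= 0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def paired_bootstrap_t(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PairedTestResult:
    """Paired t-test with a bootstrap p-value from resampled differences."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) != len(b):
        raise LengthMismatch(f"paired samples differ in length: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 3:
        raise TooFewPairs(f"need at least 3 pairs, got {n}")
    diffs = a - b
    mean_diff = diffs.mean()
    sd_diff = diffs.std(ddof=1)
    if sd_diff == 0:
        t_stat = 0.0
        ci = (mean_diff, mean_diff)
    else:
        se = sd_diff / np.sqrt(n)
        t_stat = mean_diff / se
        q = sps.t.ppf(0.975, df=n - 1)
        ci = (mean_diff - q * se, mean_diff + q * se)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = diffs[idx].mean(axis=1)
    p = _two_sided_percentile_p(boot_means)
    return PairedTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        t=float(t_stat),
        p=p,
        d=float(cohens_d_paired(t_stat, n)),
        n=n,
    )


def independent_bootstrap_t(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PairedTestResult:
    """Welch t-test with a group-wise bootstrap p and pooled-SD effect size."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise TooFewValues("each group needs at least 2 values")
    welch = sps.ttest_ind(a, b, equal_var=False)
    mean_diff = a.mean() - b.mean()
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se > 0:
        q = sps.t.ppf(0.975, df=welch.df)
        ci = (mean_diff - q * se, mean_diff + q * se)
    else:
        ci = (mean_diff, mean_diff)
    rng = np.random.default_rng(seed)
    boot_a = a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
    boot_b = b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
    p = _two_sided_percentile_p(boot_a - boot_b)
    sd = pooled_sd(a, b)
    d = abs(mean_diff) / sd if sd > 0 else 0.0
    return PairedTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        t=float(welch.statistic),
        p=p,
        d=float(d),
        n=len(a) + len(b),
    )


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sample permutation test on the difference of means (two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise TooFewValues("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise DegenerateGroups("all values identical; permutation distribution is degenerate")
    observed = a.mean() - b.mean()
    na = len(a)
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: argsort of uniforms gives uniform permutations
    order = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm_vals = pooled[order]
    perm_stats = perm_vals[:, :na].mean(axis=1) - perm_vals[:, na:].mean(axis=1)
    p = (np.sum(np.abs(perm_stats) >= abs(observed)) + 1) / (n_perm + 1)
    sd = pooled_sd(a, b) if len(a) > 1 and len(b) > 1 else 0.0
    d = abs(observed) / sd if sd > 0 else np.inf
    return PermutationResult(
        observed=float(observed), p=float(p), n_perm=n_perm, d=float(d), seed=seed
    )
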
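"""Bootstrap confidence intervals and paired tests on per-cell metric vectors.

The inferential toolkit used throughout the pipeline: percentile bootstrap
(1000 repetitions, alpha = 0.05 by default) for confidence intervals, and the
Wilcoxon sign-rank, sign and paired t tests against a zero-median/zero-mean
null for the paired condition contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

DEFAULT_N_BOOT = 1000
DEFAULT_ALPHA = 0.05

#: Sample size up to which the exact sign-rank distribution is used.
SIGNRANK_EXACT_N = 25

_STATS = {"mean": np.mean, "median": np.median}


@dataclass
class EstimateWithCI:
    """Point estimate with percentile-bootstrap CI and optional p-values."""

    point: float
    ci_lo: float
    ci_hi: float
    n: int
    alpha: float = DEFAULT_ALPHA
    n_boot: int = DEFAULT_N_BOOT
    p_signrank: float | None = None
    p_signtest: float | None = None
    p_ttest: float | None = None

    def covers(self, value: float) -> bool:
        return self.ci_lo <= value <= self.ci_hi


def bootstrap_ci(
    x: np.ndarray,
    stat: str = "mean",
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
) -> EstimateWithCI:
    """Percentile bootstrap CI of the mean or median of ``x``.

    Resamples ``x`` with replacement ``n_boot`` times and takes the
    (alpha/2, 1 - alpha/2) quantiles of the resampled statistic.  Seeded and
    reproducible.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"bootstrap CI undefined for n={x.size} (< 2)")
    fn = _STATS[stat]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = fn(x[idx], axis=1)
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return EstimateWithCI(
        point=float(fn(x)), ci_lo=float(lo), ci_hi=float(hi),
        n=int(x.size), alpha=alpha, n_boot=n_boot,
    )


def signrank_p(x: np.ndarray) -> float:
    """Two-sided Wilcoxon sign-rank p-value against a zero-median null.

    Zeros are dropped; the exact null distribution is used for n <= 25 (no
    ties), the continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    if x.size == 0:
        raise ValueError("sign-rank undefined: all values are zero")
    has_ties = np.unique(np.abs(x)).size < x.size
    method = "exact" if (x.size <= SIGNRANK_EXACT_N and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(x, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def signtest_p(x: np.ndarray) -> float:
    """Two-sided exact sign-test p-value against a zero-median null.

    Computed from binomial tail arithmetic directly: with k positive signs of
    n nonzero values, p = 2 * P(Binom(n, 1/2) >= max(k, n-k)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    n = x.size
    if n == 0:
        raise ValueError("sign test undefined: all values are zero")
    k = int(np.sum(x > 0))
    k_hi = max(k, n - k)
    tail = sum(math.comb(n, j) for j in range(k_hi, n + 1)) / 2.0 ** n
    return float(min(1.0, 2.0 * tail))


def paired_t_p(x: np.ndarray) -> float:
    """Two-sided one-sample t-test p-value against a zero-mean null."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"t-test undefined for n={x.size} (< 2)")
    return float(scipy.stats.ttest_1samp(x, 0.0).pvalue)


def estimate(
    x: np.ndarray,
    stat: str = "mean",
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
    with_tests: bool = True,
) -> EstimateWithCI:
    """Bootstrap CI plus the three paired tests on one metric vector.

    For n < 2 returns a flagged point estimate (NaN CI) rather than raising,
    matching the pipeline's behaviour on degenerate cell sets.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return EstimateWithCI(
            point=float(_STATS[stat](x)) if x.size else float("nan"),
            ci_lo=float("nan"), ci_hi=float("nan"),
            n=int(x.size), alpha=alpha, n_boot=n_boot,
        )
    est = bootstrap_ci(x, stat=stat, n_boot=n_boot, alpha=alpha, seed=seed)
    if with_tests:
        nonzero = np.any(x != 0)
        est.p_signrank = signrank_p(x) if nonzero else None
        est.p_signtest = signtest_p(x) if nonzero else None
        est.p_ttest = paired_t_p(x)
    return est
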
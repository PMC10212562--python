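"""Nonparametric tests: two-tailed Monte-Carlo permutation test and sign test.

The permutation test shuffles group labels ``n_perm`` times (default 10,000)
and reports the fraction of permutations whose |statistic| is at least the
observed |statistic|. When no permutation qualifies the p-value is reported
as a bound (p < 1/n_perm, printed as "p<0.0001" at the default count); the
observed arrangement is not counted among the permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as _stats

from .core import ValidationError

__all__ = ["TestResult", "permutation_test", "sign_test", "diff_of_means"]


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: float
    n_permutations: int = 0
    is_bound: bool = False       # True when reported as p < 1/n_perm

    def formatted_p(self) -> str:
        if self.is_bound:
            return f"p<{1.0 / self.n_permutations:g}"
        return f"p={self.p_value:.3g}"

    def to_dict(self) -> dict:
        return {"p_value": self.p_value, "statistic": self.statistic,
                "n_permutations": self.n_permutations, "is_bound": self.is_bound}


def diff_of_means(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(x) - np.mean(y))


def permutation_test(
    x, y,
    statistic: Callable[[np.ndarray, np.ndarray], float] = diff_of_means,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Two-tailed Monte-Carlo permutation test on two independent groups.

    Two-tailedness is implemented as |statistic| exceedance. Zero qualifying
    permutations returns ``is_bound=True`` with the 1/n_perm bound as the
    p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be nonempty")
    observed = statistic(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    count = 0
    if statistic is diff_of_means:
        # vectorized label shuffles, chunked to bound memory
        done = 0
        while done < n_perm:
            chunk = min(2000, n_perm - done)
            idx = np.argsort(rng.random((chunk, pooled.size)), axis=1)
            perm = pooled[idx]
            stats = perm[:, :x.size].mean(axis=1) - perm[:, x.size:].mean(axis=1)
            count += int(np.sum(np.abs(stats) >= abs(observed)))
            done += chunk
    else:
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(statistic(perm[:x.size], perm[x.size:])) >= abs(observed):
                count += 1
    if count == 0:
        return TestResult(p_value=1.0 / n_perm, statistic=observed,
                          n_permutations=n_perm, is_bound=True)
    return TestResult(p_value=count / n_perm, statistic=observed,
                      n_permutations=n_perm)


def sign_test(n_positive: int, n_negative: int) -> TestResult:
    """Two-sided exact sign test (ties excluded upstream).

    p = 2 * P(X <= min(n+, n-)) under Binomial(n+ + n-, 1/2), capped at 1.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValidationError("counts must be non-negative")
    n = n_positive + n_negative
    if n == 0:
        raise ValidationError("need at least one non-tied observation")
    k = min(n_positive, n_negative)
    p = min(1.0, 2.0 * float(_stats.binom.cdf(k, n, 0.5)))
    return TestResult(p_value=p, statistic=float(n_positive - n_negative))
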
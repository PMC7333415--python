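"""Summary statistics and two-sample tests for setup comparison.

Recorded and synthetic surgery logs are compared the way the clinical
evaluation compares setups: mean +/- sample SD summaries and a two-tailed
two-sample t-test, Welch's by default (the recorded cohorts have unequal
sizes and no reason to share a variance), with Student's pooled variant
selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["SampleSummary", "TestResult", "summarize", "t_test_two_tailed", "rank_setups"]


@dataclass(frozen=True)
class SampleSummary:
    n: int
    mean: float
    sd: float  # sample standard deviation, n-1 denominator

    def __str__(self) -> str:
        return f"{self.mean:.1f} +/- {self.sd:.1f} (n={self.n})"


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_two_tailed: float


def summarize(sample: Sequence[float]) -> SampleSummary:
    """Mean and n-1 sample SD; requires at least two observations."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError(f"summarize: need n >= 2 observations, got {x.size}")
    return SampleSummary(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def t_test_two_tailed(
    a: Sequence[float], b: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Two-tailed two-sample t-test (Welch by default, Student selectable).

    Degenerate zero-variance inputs follow the documented convention:
    equal means give p = 1 (no evidence of a difference), unequal means
    give p = 0 (the samples are deterministically different).
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"variant must be 'welch' or 'student', got {variant!r}")
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("t_test_two_tailed: each sample needs n >= 2")
    if xa.std(ddof=1) == 0.0 and xb.std(ddof=1) == 0.0:
        df = float(xa.size + xb.size - 2)
        if xa.mean() == xb.mean():
            return TestResult(t_statistic=0.0, degrees_of_freedom=df, p_two_tailed=1.0)
        t = math.inf if xa.mean() > xb.mean() else -math.inf
        return TestResult(t_statistic=t, degrees_of_freedom=df, p_two_tailed=0.0)
    res = _sps.ttest_ind(xa, xb, equal_var=(variant == "student"))
    return TestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_two_tailed=float(res.pvalue),
    )


def rank_setups(metric: Mapping[str, float], lower_is_better: bool = True) -> list[str]:
    """Order setup ids by a metric; stable, ties keep input order."""
    if not metric:
        raise ValueError("rank_setups: empty metric mapping")
    items = list(metric.items())
    return [k for k, v in sorted(items, key=lambda kv: (kv[1] if lower_is_better else -kv[1]))]
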
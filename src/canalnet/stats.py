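"""Comparison statistics: paired t-tests, Bland–Altman, power analysis.

These are the statistical procedures the evaluation harness applies to
per-case metric tables: paired two-tailed t-tests between models measured on
the same cases, Bland–Altman agreement between predicted and true voxel
counts, and the a-priori sample-size computation for detecting a given
accuracy difference between two models (two-sample two-tailed t-test power,
via the noncentral t distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length measurement sequences on the same subjects."""

    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or len(a) != len(b) or len(a) < 2:
            raise ValueError("paired sample needs two equal-length 1D "
                             "sequences of length >= 2")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class SampleSizeSpec:
    """A-priori power analysis for a two-sample two-tailed t design."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")


def paired_t_test(sample: PairedSample) -> tuple[float, int, float]:
    """Paired two-tailed t-test; returns (t, df, p)."""
    d = sample.differences
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            # identical samples: no evidence of any difference
            return 0.0, len(d) - 1, 1.0
        raise ValueError("differences have zero variance; paired t-test is "
                         "degenerate")
    res = sps.ttest_rel(sample.values_a, sample.values_b)
    return float(res.statistic), int(res.df), float(res.pvalue)


def bland_altman(sample: PairedSample, loa_multiplier: float = 1.96
                 ) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of paired measurements."""
    d = sample.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        means=(sample.values_a + sample.values_b) / 2.0,
        diffs=d,
    )


def two_sample_power(n_per_group: int, effect_size: float, alpha: float) -> float:
    """Exact power of the two-sample two-tailed t-test at equal group size n.

    Uses the noncentral t distribution with df = 2n - 2 and noncentrality
    d * sqrt(n/2).
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = effect_size * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def required_sample_size(spec: SampleSizeSpec, max_n: int = 10 ** 6) -> int:
    """Total N (both groups) for the two-sample two-tailed t design.

    Finds the smallest equal per-group n whose exact noncentral-t power
    reaches the target, seeded by the continuous statsmodels solution, and
    returns 2n.
    """
    approx = TTestIndPower().solve_power(effect_size=spec.effect_size,
                                         alpha=spec.alpha, power=spec.power,
                                         alternative="two-sided")
    if not np.isfinite(approx) or approx > max_n:
        raise ValueError("target power unreachable at a feasible sample size")
    n = max(2, math.ceil(approx - 1e-9))
    while two_sample_power(n, spec.effect_size, spec.alpha) < spec.power:
        n += 1
        if n > max_n:
            raise ValueError("target power unreachable at a feasible sample size")
    while n > 2 and two_sample_power(n - 1, spec.effect_size, spec.alpha) >= spec.power:
        n -= 1
    return 2 * n
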
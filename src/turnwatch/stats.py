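"""Inferential pieces of the pre/post comparison.

Covers the study's three computations: the margin-of-error sample-size
formula n = Z^2 sd^2 / e^2, the two-sample t test on per-patient
compliance fractions (Student by default, Welch available), and the
Pearson chi-square test of independence on a 2x2 sex-by-phase table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the margin-of-error sample-size formula.

    ``z`` is the standard-normal quantile for the confidence level
    (1.96 for 95%), ``sd`` the assumed standard deviation of the outcome
    fraction, and ``e`` the desired margin of error, both on the 0-1
    scale.
    """

    z: float = 1.96
    sd: float = 0.5
    e: float = 0.123

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not 0 < self.e < 1:
            raise ValueError("e must lie in (0, 1)")


def sample_size(
    inputs: SampleSizeInputs = SampleSizeInputs(), method: str = "floor"
) -> int:
    """Target sample size n = Z^2 sd^2 / e^2.

    The fractional result is truncated by default (the convention that
    yields a target of 63 from z=1.96, sd=0.5, e=0.123); pass
    ``method="ceil"`` for the conservative rounding.  A tiny relative
    tolerance absorbs floating-point error so exact ratios stay exact.
    """
    x = (inputs.z * inputs.sd / inputs.e) ** 2
    x_adj = x * (1.0 + 1e-12) + 1e-9
    if method == "floor":
        return math.floor(x_adj)
    if method == "ceil":
        return math.ceil(x - 1e-9)
    raise ValueError("method must be 'floor' or 'ceil'")


@dataclass(frozen=True)
class TestResult:
    """Result of one hypothesis test."""

    test: str
    statistic: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    n: tuple[int, int]
    tails: str = "two"
    note: str | None = None


def two_sample_t(
    a, b, variant: str = "student", tails: str = "two"
) -> TestResult:
    """Two-sample t test comparing group ``a`` with group ``b``.

    ``variant="student"`` pools the variances, ``"welch"`` does not.
    ``tails="two"`` is the default two-sided test; ``tails="one"`` is the
    one-sided test of the alternative mean(b) > mean(a) (an improvement
    from the first group to the second).

    Degenerate inputs where both groups have zero variance are handled in
    the limit: equal means give statistic 0 and p = 1; unequal means give
    an infinite statistic and p = 0.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs at least 2 observations, got {a.size} and {b.size}"
        )
    mean_a, mean_b = float(a.mean()), float(b.mean())
    df_pooled = float(a.size + b.size - 2)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if mean_a == mean_b:
            stat, p = 0.0, 1.0
        else:
            stat = math.copysign(math.inf, mean_a - mean_b)
            p = 0.0
        return TestResult(
            test="t",
            statistic=stat,
            df=df_pooled,
            p_value=p,
            group_means=(mean_a, mean_b),
            n=(int(a.size), int(b.size)),
            tails=tails,
            note="zero variance in both groups; limiting values reported",
        )
    alternative = "two-sided" if tails == "two" else "less"
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"), alternative=alternative)
    return TestResult(
        test="t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_means=(mean_a, mean_b),
        n=(int(a.size), int(b.size)),
        tails=tails,
    )


def chi_square_2x2(counts) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table.

    ``counts`` is row-per-group, e.g. ``[[females_a, males_a],
    [females_b, males_b]]``.  No continuity correction is applied;
    df = 1.  ``group_means`` reports the first-column proportion of each
    row.  Raises on any zero marginal.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"counts must be a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square test undefined with a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    row_tot = table.sum(axis=1)
    return TestResult(
        test="chi2",
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(res.pvalue),
        group_means=(float(table[0, 0] / row_tot[0]), float(table[1, 0] / row_tot[1])),
        n=(int(row_tot[0]), int(row_tot[1])),
        tails="two",
    )
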
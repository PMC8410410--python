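"""Per-arm summaries and two-sample comparisons of marker expression.

A "study arm" is one group of samples (cases or controls) reduced to its
sample size, mean and sample standard deviation — the form in which public
expression datasets are usually tabulated.  Group comparisons use Welch's
unequal-variance t-test, which is the convention for clinical-parameter
tables of marker expression (tumor vs normal, stage III–IV vs I–II, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ArmSummary",
    "TestResult",
    "summarize_arm",
    "welch_t",
    "clinical_association",
    "AssociationRow",
]


@dataclass(frozen=True)
class ArmSummary:
    """Sample count, mean and sample SD (n−1 denominator) of one study arm."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"arm needs at least one sample, got n={self.n}")
        if not math.isfinite(self.mean):
            raise ValueError("arm mean must be finite")
        if not (self.sd >= 0):
            raise ValueError(f"arm sd must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test.

    ``statistic`` is reported as an absolute value with the comparison's
    direction in ``direction`` (+1 when the first arm's mean is larger,
    −1 when smaller, 0 when equal), matching how clinical tables print
    positive T values.
    """

    statistic: float
    df: float
    p: float
    method: str
    direction: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p}")


def summarize_arm(values: Iterable[float]) -> ArmSummary:
    """Reduce raw expression values of one arm to (n, mean, sd).

    The SD uses the n−1 denominator; a single value yields sd = 0.
    Raises ``ValueError`` on empty or non-finite input.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty arm")
    if not np.all(np.isfinite(arr)):
        raise ValueError("arm values must be finite")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ArmSummary(n=int(arr.size), mean=float(arr.mean()), sd=sd)


def welch_t(a: ArmSummary, b: ArmSummary) -> TestResult:
    """Welch's unequal-variance t-test from two arm summaries.

    statistic = |m_a − m_b| / sqrt(s_a²/n_a + s_b²/n_b), with
    Welch–Satterthwaite degrees of freedom and a two-sided p-value.
    Both arms need n ≥ 2 (the variance of a single observation is
    undefined).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("Welch's t requires n >= 2 in both arms")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0.0:
        # both arms constant: identical means give t=0, otherwise infinite
        if a.mean == b.mean:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, "welch_t", 0)
        raise ValueError("zero variance in both arms with unequal means")
    t = (a.mean - b.mean) / math.sqrt(se2)
    denom = va**2 / (a.n - 1) + vb**2 / (b.n - 1)
    # denom can underflow to 0 for near-constant arms; use the pooled df limit
    df = se2**2 / denom if denom > 0 else float(a.n + b.n - 2)
    p = float(2.0 * stats.t.sf(abs(t), df))
    direction = 0 if t == 0 else (1 if t > 0 else -1)
    return TestResult(abs(t), float(df), p, "welch_t", direction)


@dataclass(frozen=True)
class AssociationRow:
    """One clinical-parameter comparison: both arm summaries plus the test.

    ``test`` is None (with ``flag`` set) when either level has fewer than
    two usable samples.
    """

    parameter: str
    level_a: str
    level_b: str
    arm_a: ArmSummary
    arm_b: ArmSummary
    test: TestResult | None
    flag: str = ""


def clinical_association(
    expr: pd.DataFrame,
    strata: pd.DataFrame,
    parameter: str,
    grouping: Mapping[str, Sequence[str]],
) -> AssociationRow:
    """Compare marker expression between two clinical strata.

    Parameters
    ----------
    expr : DataFrame with columns ``sample_id`` and ``value``.
    strata : DataFrame with columns ``sample_id`` and ``parameter``
        (the clinical table; ``parameter`` names one of its columns).
    parameter : column of ``strata`` holding the categorical level.
    grouping : mapping of exactly two output labels to the stratum values
        they pool, e.g. ``{"III-IV": ["III", "IV"], "I-II": ["I", "II"]}``.

    Levels are joined on ``sample_id``; each output arm must be non-empty.
    If an arm has n < 2 the row is still emitted, with the test omitted
    and flagged.
    """
    if len(grouping) != 2:
        raise ValueError("grouping must define exactly two levels")
    merged = expr.merge(strata[["sample_id", parameter]], on="sample_id")
    (name_a, lv_a), (name_b, lv_b) = grouping.items()
    vals_a = merged.loc[merged[parameter].isin(list(lv_a)), "value"]
    vals_b = merged.loc[merged[parameter].isin(list(lv_b)), "value"]
    if vals_a.empty or vals_b.empty:
        raise ValueError(f"empty stratum for parameter {parameter!r}")
    arm_a, arm_b = summarize_arm(vals_a), summarize_arm(vals_b)
    if arm_a.n < 2 or arm_b.n < 2:
        return AssociationRow(
            parameter, name_a, name_b, arm_a, arm_b, None, flag="n<2: test omitted"
        )
    return AssociationRow(parameter, name_a, name_b, arm_a, arm_b, welch_t(arm_a, arm_b))
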
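"""Standardized-mean-difference meta-analysis across independent datasets.

Each dataset contributes a standardized mean difference (SMD) between its
case and control arms — Cohen's d, or Hedges' g with the small-sample bias
correction J.  Studies are pooled by inverse-variance weighting under a
fixed-effect model, or under a DerSimonian–Laird random-effects model when
between-study heterogeneity (Cochran's Q, Higgins' I²) is substantial.
Leave-one-out sensitivity analysis, subgroup pooling and Begg's
rank-correlation test for publication bias complete the workflow.

The default SMD measure is Cohen's d with variance
``(n1+n2)/(n1·n2) + d²/(2(n1+n2))``, the convention of the classic Stata
``metan`` command; Hedges' g (``measure="hedges"``) multiplies d by
``J = 1 − 3/(4(n1+n2−2)−1)`` and uses the analogous variance with g.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .summary import ArmSummary, TestResult

__all__ = [
    "EffectSize",
    "PooledEffect",
    "cohens_d",
    "hedges_g",
    "smd_effect",
    "effect_sizes",
    "pool_fixed",
    "pool_random",
    "leave_one_out",
    "subgroup_pool",
    "beggs_test",
]

Z95 = 1.96  # normal quantile for the conventional 95% Wald interval


@dataclass(frozen=True)
class EffectSize:
    """Per-study standardized mean difference and its sampling variance."""

    study_id: str
    g: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise ValueError(f"{self.study_id}: effect variance must be > 0")


@dataclass(frozen=True)
class PooledEffect:
    """Pooled SMD with heterogeneity diagnostics.

    ``Q`` and ``I2`` always refer to the fixed-effect (inverse-variance)
    weights, as conventionally reported; ``tau2`` is 0 under the fixed
    model and the DerSimonian–Laird moment estimate under the random one.
    """

    estimate: float
    ci_low: float
    ci_high: float
    se: float
    Q: float
    df: int
    I2: float
    tau2: float
    model: str
    k: int
    p: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI does not bracket the estimate")
        if not (0.0 <= self.I2 < 100.0):
            raise ValueError(f"I2 out of [0,100): {self.I2}")


def _pooled_sd(case: ArmSummary, control: ArmSummary) -> float:
    n1, n2 = case.n, control.n
    if n1 < 2 or n2 < 2:
        raise ValueError("SMD requires n >= 2 in both arms")
    sp2 = ((n1 - 1) * case.sd**2 + (n2 - 1) * control.sd**2) / (n1 + n2 - 2)
    sp = math.sqrt(sp2)
    if sp == 0.0:
        raise ValueError("pooled SD is zero: SMD undefined")
    return sp


def cohens_d(case: ArmSummary, control: ArmSummary, study_id: str = "") -> EffectSize:
    """Cohen's d = (mean_case − mean_control)/s_pooled and its variance."""
    n1, n2 = case.n, control.n
    d = (case.mean - control.mean) / _pooled_sd(case, control)
    v = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
    return EffectSize(study_id, d, v)


def hedges_g(case: ArmSummary, control: ArmSummary, study_id: str = "") -> EffectSize:
    """Hedges' g: Cohen's d shrunk by the small-sample factor J.

    J = 1 − 3/(4(n1+n2−2)−1); variance (n1+n2)/(n1·n2) + g²/(2(n1+n2)).
    """
    n1, n2 = case.n, control.n
    d = (case.mean - control.mean) / _pooled_sd(case, control)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = j * d
    v = (n1 + n2) / (n1 * n2) + g**2 / (2 * (n1 + n2))
    return EffectSize(study_id, g, v)


_MEASURES = {"cohen": cohens_d, "hedges": hedges_g}


def smd_effect(
    case: ArmSummary, control: ArmSummary, study_id: str = "", measure: str = "cohen"
) -> EffectSize:
    """Standardized mean difference under the chosen measure."""
    try:
        fn = _MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown SMD measure {measure!r}") from None
    return fn(case, control, study_id)


def effect_sizes(records, measure: str = "cohen") -> list[EffectSize]:
    """Per-study SMDs for an iterable of StudyRecord-like objects.

    Each record needs ``study_id``, ``case`` and ``control`` attributes.
    """
    return [smd_effect(r.case, r.control, r.study_id, measure) for r in records]


def _check_effects(effects: Sequence[EffectSize], k_min: int) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) < k_min:
        raise ValueError(f"need at least {k_min} effects, got {len(effects)}")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return g, v


def _heterogeneity(g: np.ndarray, v: np.ndarray) -> tuple[float, int, float]:
    w = 1.0 / v
    est = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - est) ** 2))
    df = len(g) - 1
    i2 = 0.0 if (df == 0 or q <= df) else (q - df) / q * 100.0
    return q, df, i2


def pool_fixed(effects: Sequence[EffectSize]) -> PooledEffect:
    """Inverse-variance fixed-effect pooling with Wald 95% CI."""
    g, v = _check_effects(effects, 1)
    w = 1.0 / v
    est = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q, df, i2 = _heterogeneity(g, v)
    p = float(2.0 * stats.norm.sf(abs(est / se)))
    return PooledEffect(est, est - Z95 * se, est + Z95 * se, se, q, df, i2, 0.0, "fixed", len(g), p)


def pool_random(effects: Sequence[EffectSize]) -> PooledEffect:
    """DerSimonian–Laird random-effects pooling.

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with fixed-effect weights,
    then re-weighting by 1/(v + τ²).  Q and I² reported from the
    fixed-effect weights.
    """
    g, v = _check_effects(effects, 2)
    w = 1.0 / v
    q, df, i2 = _heterogeneity(g, v)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    ws = 1.0 / (v + tau2)
    est = float(np.sum(ws * g) / np.sum(ws))
    se = float(1.0 / math.sqrt(np.sum(ws)))
    p = float(2.0 * stats.norm.sf(abs(est / se)))
    return PooledEffect(est, est - Z95 * se, est + Z95 * se, se, q, df, i2, tau2, "random", len(g), p)


def leave_one_out(effects: Sequence[EffectSize]) -> list[tuple[str, PooledEffect]]:
    """Random-effects re-pooling with each study omitted in turn."""
    if len(effects) < 3:
        raise ValueError("leave-one-out needs at least 3 effects")
    out = []
    for i, e in enumerate(effects):
        rest = [x for j, x in enumerate(effects) if j != i]
        out.append((e.study_id, pool_random(rest)))
    return out


def subgroup_pool(
    effects: Sequence[EffectSize], labels: Mapping[str, str]
) -> dict[str, PooledEffect]:
    """Random-effects pooling within each subgroup label, plus overall.

    ``labels`` maps study_id → group token; every study must be labelled.
    Subgroups of size one fall back to the fixed (single-study) result.
    The overall pooling is returned under the key ``"overall"``.
    """
    missing = [e.study_id for e in effects if e.study_id not in labels]
    if missing:
        raise ValueError(f"unlabelled studies: {missing}")
    groups: dict[str, list[EffectSize]] = {}
    for e in effects:
        groups.setdefault(labels[e.study_id], []).append(e)
    out = {}
    for name, subset in groups.items():
        out[name] = pool_random(subset) if len(subset) >= 2 else pool_fixed(subset)
    out["overall"] = pool_random(list(effects))
    return out


def _kendall_s(x: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Kendall score S = concordant − discordant, and tie-corrected Var(S)."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))

    def tie_terms(z: np.ndarray) -> tuple[float, float, float]:
        _, counts = np.unique(z, return_counts=True)
        t1 = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
        t2 = float(np.sum(counts * (counts - 1) * (counts - 2)))
        t3 = float(np.sum(counts * (counts - 1)))
        return t1, t2, t3

    x1, x2, x3 = tie_terms(x)
    y1, y2, y3 = tie_terms(y)
    var = (
        (n * (n - 1) * (2 * n + 5) - x1 - y1) / 18.0
        + x2 * y2 / (9.0 * n * (n - 1) * (n - 2))
        + x3 * y3 / (2.0 * n * (n - 1))
    )
    return s, var


def beggs_test(effects: Sequence[EffectSize], exact_max_k: int = 8) -> TestResult:
    """Begg's rank-correlation test for small-study (publication) bias.

    Standardized deviates t_i = (g_i − ĝ_fixed)/sqrt(v_i − 1/Σw) are rank-
    correlated (Kendall) with the variances v_i.  For k ≤ ``exact_max_k``
    the p-value is the exact permutation tail of the Kendall score;
    beyond that, the tie-corrected normal approximation with continuity
    correction is used.  If every variance is tied the statistic is
    undefined and p = 1 is reported with method ``"begg_ties"``.
    """
    g, v = _check_effects(effects, 3)
    k = len(g)
    w = 1.0 / v
    fixed = float(np.sum(w * g) / np.sum(w))
    pooled_var = 1.0 / float(np.sum(w))
    adj = v - pooled_var
    if np.any(adj <= 0):
        eps = 1e-12
        adj = np.maximum(adj, eps)
    t = (g - fixed) / np.sqrt(adj)

    if np.unique(v).size == 1:
        return TestResult(0.0, float(k), 1.0, "begg_ties", 0)

    s_obs, var_s = _kendall_s(t, v)
    tau = stats.kendalltau(t, v).statistic

    if k <= exact_max_k:
        # exact permutation null of the Kendall score given the tie pattern
        count = 0
        total = 0
        for perm in itertools.permutations(range(k)):
            s_p, _ = _kendall_s(t[list(perm)], v)
            total += 1
            if abs(s_p) >= abs(s_obs):
                count += 1
        p = count / total
        return TestResult(float(tau), float(k), float(p), "begg_exact",
                          0 if s_obs == 0 else int(np.sign(s_obs)))

    z = 0.0 if abs(s_obs) <= 1 else (abs(s_obs) - 1.0) / math.sqrt(var_s)
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return TestResult(float(tau), float(k), p, "begg_normal",
                      0 if s_obs == 0 else int(np.sign(s_obs)))
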
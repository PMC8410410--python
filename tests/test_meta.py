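import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metamarker.meta import (
    EffectSize,
    beggs_test,
    cohens_d,
    effect_sizes,
    hedges_g,
    leave_one_out,
    pool_fixed,
    pool_random,
    smd_effect,
    subgroup_pool,
)
from metamarker.summary import ArmSummary

from conftest import random_effects

effect_lists = st.lists(
    st.tuples(
        st.floats(-2, 2, allow_nan=False), st.floats(0.01, 1.0, allow_nan=False)
    ),
    min_size=1,
    max_size=5,
)


def make_effects(pairs):
    return [EffectSize(f"S{i}", g, v) for i, (g, v) in enumerate(pairs)]


# ---------------------------------------------------------------- effect sizes

def test_hedges_g_reference_row():
    # 40 vs 40 arms with ~3.3-unit separation: g close to -1.45
    e = hedges_g(ArmSummary(40, 8.6857, 2.4182), ArmSummary(40, 11.9760, 2.0615))
    assert e.g == pytest.approx(-1.45, abs=0.01)


def test_equal_means_give_zero_effect_and_analytic_variance():
    e = hedges_g(ArmSummary(12, 3.0, 1.0), ArmSummary(8, 3.0, 2.0))
    assert e.g == 0.0
    assert e.variance == pytest.approx((12 + 8) / (12 * 8))


def test_swapping_arms_negates_effect():
    a, b = ArmSummary(9, 4.4, 1.2), ArmSummary(14, 6.0, 0.8)
    for fn in (hedges_g, cohens_d):
        assert fn(a, b).g == pytest.approx(-fn(b, a).g, rel=1e-14)
        assert fn(a, b).variance == pytest.approx(fn(b, a).variance, rel=1e-14)


def test_hedges_shrinks_cohen_toward_zero():
    a, b = ArmSummary(5, 2.0, 1.0), ArmSummary(6, 4.0, 1.0)
    assert abs(hedges_g(a, b).g) < abs(cohens_d(a, b).g)


def test_zero_pooled_sd_rejected():
    with pytest.raises(ValueError):
        cohens_d(ArmSummary(5, 1.0, 0.0), ArmSummary(5, 2.0, 0.0))
    with pytest.raises(ValueError):
        smd_effect(ArmSummary(5, 1.0, 1.0), ArmSummary(5, 2.0, 1.0), measure="nope")


# -------------------------------------------------------------------- pooling

@given(pairs=effect_lists)
@settings(max_examples=100, deadline=None)
def test_fixed_pooling_equals_brute_force_weighted_mean(pairs):
    effects = make_effects(pairs)
    pooled = pool_fixed(effects)
    num = sum(g / v for g, v in pairs)
    den = sum(1 / v for g, v in pairs)
    assert pooled.estimate == pytest.approx(num / den, abs=1e-10)
    assert pooled.se == pytest.approx(1 / math.sqrt(den), abs=1e-10)


def test_single_study_pooling():
    e = EffectSize("only", -0.4, 0.09)
    pooled = pool_fixed([e])
    assert pooled.estimate == -0.4
    assert pooled.Q == 0.0
    assert pooled.ci_low == pytest.approx(-0.4 - 1.96 * 0.3)


def test_two_equal_variance_studies_pool_to_arithmetic_mean():
    pooled = pool_fixed([EffectSize("a", -1.0, 0.2), EffectSize("b", 0.4, 0.2)])
    assert pooled.estimate == pytest.approx(-0.3)


def test_homogeneous_effects_make_random_equal_fixed():
    effects = [EffectSize(f"s{i}", -0.5, v) for i, v in enumerate([0.1, 0.2, 0.4])]
    f, r = pool_fixed(effects), pool_random(effects)
    assert f.Q == pytest.approx(0.0, abs=1e-12)
    assert f.I2 == 0.0
    assert r.tau2 == 0.0
    assert r.estimate == pytest.approx(f.estimate)
    assert (r.ci_low, r.ci_high) == pytest.approx((f.ci_low, f.ci_high))


def test_dersimonian_laird_matches_hand_computation():
    """Three-study DL pooling against a step-by-step spreadsheet-style oracle."""
    effects = make_effects([(-0.8, 0.04), (-0.1, 0.10), (0.3, 0.25)])
    w = np.array([25.0, 10.0, 4.0])
    g = np.array([-0.8, -0.1, 0.3])
    fixed = (w * g).sum() / w.sum()
    q = (w * (g - fixed) ** 2).sum()
    tau2 = max(0.0, (q - 2) / (w.sum() - (w**2).sum() / w.sum()))
    ws = 1 / (1 / w + tau2)
    expected = (ws * g).sum() / ws.sum()
    pooled = pool_random(effects)
    assert pooled.tau2 == pytest.approx(tau2, rel=1e-12)
    assert pooled.estimate == pytest.approx(expected, rel=1e-12)


def test_random_pooling_cross_checked_against_statsmodels(all_records):
    statsmodels = pytest.importorskip("statsmodels.stats.meta_analysis")
    effects = effect_sizes(all_records)
    g = np.array([e.g for e in effects])
    v = np.array([e.variance for e in effects])
    res = statsmodels.combine_effects(g, v, method_re="chi2")
    ours_f, ours_r = pool_fixed(effects), pool_random(effects)
    assert ours_f.estimate == pytest.approx(res.mean_effect_fe, rel=1e-10)
    assert ours_r.estimate == pytest.approx(res.mean_effect_re, rel=1e-10)
    assert ours_r.tau2 == pytest.approx(res.tau2, rel=1e-10)


@given(pairs=st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)), min_size=2, max_size=6))
@settings(max_examples=60, deadline=None)
def test_negating_effects_flips_both_pooled_estimates(pairs):
    effects = make_effects(pairs)
    negated = [EffectSize(e.study_id, -e.g, e.variance) for e in effects]
    for pool in (pool_fixed, pool_random):
        a, b = pool(effects), pool(negated)
        assert a.estimate == pytest.approx(-b.estimate, abs=1e-10)
        assert a.ci_low == pytest.approx(-b.ci_high, abs=1e-10)
        assert a.Q == pytest.approx(b.Q, abs=1e-9)


@given(pairs=effect_lists, extra=st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)))
@settings(max_examples=60, deadline=None)
def test_fixed_ci_width_shrinks_with_additional_study(pairs, extra):
    effects = make_effects(pairs)
    wider = pool_fixed(effects)
    narrower = pool_fixed(effects + [EffectSize("new", *extra)])
    assert (narrower.ci_high - narrower.ci_low) < (wider.ci_high - wider.ci_low)


# ----------------------------------------------------------------- sensitivity

def test_leave_one_out_identical_studies():
    effects = [EffectSize(f"s{i}", -0.5, 0.1) for i in range(3)]
    rows = leave_one_out(effects)
    assert [sid for sid, _ in rows] == ["s0", "s1", "s2"]
    estimates = {round(p.estimate, 12) for _, p in rows}
    assert estimates == {-0.5}
    with pytest.raises(ValueError):
        leave_one_out(effects[:2])


def test_leave_one_out_dropping_largest_outlier_lowers_q(all_records):
    effects = effect_sizes(all_records)
    full_q = pool_fixed(effects).Q
    worst = max(effects, key=lambda e: abs(e.g - pool_fixed(effects).estimate) / e.variance**0.5)
    rows = dict(leave_one_out(effects))
    assert rows[worst.study_id].Q < full_q
    assert len(rows) == 19


def test_subgroup_single_label_equals_overall(rng):
    effects = random_effects(rng, 6)
    labels = {e.study_id: "all" for e in effects}
    out = subgroup_pool(effects, labels)
    assert out["all"].estimate == pytest.approx(out["overall"].estimate)


def test_subgroup_partition_matches_subset_pooling(rng):
    effects = random_effects(rng, 6)
    labels = {e.study_id: ("A" if i < 3 else "B") for i, e in enumerate(effects)}
    out = subgroup_pool(effects, labels)
    assert out["A"].estimate == pytest.approx(pool_random(effects[:3]).estimate)
    assert out["B"].estimate == pytest.approx(pool_random(effects[3:]).estimate)
    with pytest.raises(ValueError, match="unlabelled"):
        subgroup_pool(effects, {})


# ----------------------------------------------------------------- Begg's test

def test_begg_identical_variances_reports_tie():
    effects = [EffectSize(f"s{i}", g, 0.1) for i, g in enumerate([-1, 0, 1, 2])]
    res = beggs_test(effects)
    assert res.method == "begg_ties"
    assert res.p == 1.0


def _exact_begg_oracle(t, v):
    """Permutation tail of the Kendall score, computed independently."""
    t, v = np.asarray(t), np.asarray(v)
    k = len(t)

    def score(tt):
        s = 0
        for i, j in itertools.combinations(range(k), 2):
            s += np.sign(tt[j] - tt[i]) * np.sign(v[j] - v[i])
        return s

    obs = abs(score(t))
    hits = sum(abs(score(t[list(p)])) >= obs for p in itertools.permutations(range(k)))
    return hits / math.factorial(k)


def test_begg_exact_enumeration_small_k(rng):
    for _ in range(3):
        g = rng.normal(0, 1, 4)
        v = rng.uniform(0.05, 0.5, 4)
        effects = [EffectSize(f"s{i}", float(g[i]), float(v[i])) for i in range(4)]
        res = beggs_test(effects)
        assert res.method == "begg_exact"
        w = 1 / v
        fixed = (w * g).sum() / w.sum()
        t = (g - fixed) / np.sqrt(v - 1 / w.sum())
        assert res.p == pytest.approx(_exact_begg_oracle(t, v))


def test_begg_fixture_shows_no_bias(all_records):
    effects = effect_sizes(all_records)
    res = beggs_test(effects)
    assert res.method == "begg_normal"
    assert res.p > 0.8  # no apparent small-study bias
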
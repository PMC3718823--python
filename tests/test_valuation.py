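"""SV arithmetic, discounting AUC, NTLX composite, and amount effects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coged.titration import EASY, HARD, run_titration
from coged.valuation import (
    NTLX_SCALES,
    SVCurve,
    amount_effect,
    discount_auc,
    extra_payment,
    ntlx_composite,
    subjective_value,
)


def curve(points, pid="p1", base=2.0, domain="effort"):
    return SVCurve(pid, base, points, domain=domain)


def test_subjective_value_worked_examples():
    assert subjective_value(0.98, 2.00) == pytest.approx(0.49)
    assert subjective_value(2.00, 2.00) == 1.0
    assert subjective_value(0.015625, 2.00) == 0.0078125
    with pytest.raises(ValueError):
        subjective_value(1.0, 0.0)


def test_extra_payment_premiums():
    assert extra_payment(0.49, 2.00) == pytest.approx(1.02)
    assert extra_payment(0.20, 2.00) == pytest.approx(1.60)
    assert extra_payment(1.0, 17.0) == 0.0
    with pytest.raises(ValueError):
        extra_payment(1.2, 2.0)


def test_auc_hand_computed_values():
    assert discount_auc(curve({2: 1, 3: 1, 4: 1})).auc == pytest.approx(1.0)
    assert discount_auc(curve({2: 0.8, 3: 0.5, 4: 0.2})).auc == pytest.approx(0.5)
    assert discount_auc(curve({2: 0, 3: 0, 4: 0})).auc == pytest.approx(0.0)


def test_auc_requires_two_points():
    with pytest.raises(ValueError, match=">= 2"):
        discount_auc(curve({3: 0.5}))


def test_auc_scale_invariance_under_affine_x():
    c = curve({2: 0.9, 3: 0.4, 4: 0.3})
    base = discount_auc(c).auc
    rescaled = discount_auc(c, x_spec={2: 20.0, 3: 30.0, 4: 40.0}).auc
    shifted = discount_auc(c, x_spec={2: -1.0, 3: 0.0, 4: 1.0}).auc
    assert base == pytest.approx(rescaled)
    assert base == pytest.approx(shifted)


def test_delay_auc_uses_calendar_days():
    c = curve(
        {7: 0.95, 182.5: 0.7, 365: 0.6, 1095: 0.4, 1825: 0.3, 3650: 0.2},
        domain="delay",
        base=1000.0,
    )
    r = discount_auc(c)
    x = np.array([7, 182.5, 365, 1095, 1825, 3650])
    xn = (x - 7) / (3650 - 7)
    expected = np.trapezoid([0.95, 0.7, 0.6, 0.4, 0.3, 0.2], xn)
    assert r.auc == pytest.approx(float(expected))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    svs=st.lists(st.floats(0, 1), min_size=3, max_size=3),
    bumps=st.lists(st.floats(0, 0.5), min_size=3, max_size=3),
)
def test_auc_bounds_and_pointwise_monotonicity(svs, bumps):
    lo = curve(dict(zip((2, 3, 4), svs)))
    hi_points = {k: min(1.0, v + b) for (k, v), b in zip(lo.points.items(), bumps)}
    hi = curve(hi_points)
    a_lo, a_hi = discount_auc(lo).auc, discount_auc(hi).auc
    assert 0.0 <= a_lo <= 1.0
    assert a_hi >= a_lo - 1e-12


def test_trapezoid_exact_for_linear_curves():
    for slope, intercept in [(-0.2, 0.9), (0.1, 0.3), (0.0, 0.7)]:
        pts = {n: intercept + slope * (n - 2) for n in (2, 3, 4)}
        expected = intercept + slope  # value at the midpoint N = 3
        assert discount_auc(curve(pts)).auc == pytest.approx(expected)


def test_titration_extremes_order_the_auc():
    """Always-EASY responder discounts more than always-HARD, any convention."""

    def auc_for(agent):
        pts = {
            n: run_titration(agent, n, 2.0).indifference_amount / 2.0
            for n in (2, 3, 4)
        }
        return discount_auc(curve(pts)).auc

    auc_easy = auc_for(lambda e, b, c: EASY)
    auc_hard = auc_for(lambda e, b, c: HARD)
    assert auc_easy < auc_hard
    assert auc_easy == pytest.approx(0.0078125)  # 0.015625 / 2, normalized
    assert auc_hard == pytest.approx(1.984375 / 2)


# -- NTLX -------------------------------------------------------------------


def test_ntlx_composite_constant_and_single_scale():
    all_21 = {s: {1: 21, 2: 21, 3: 21, 4: 21} for s in NTLX_SCALES}
    assert ntlx_composite(all_21) == pytest.approx(21.0)
    one_scale = {s: {1: 0, 2: 0, 3: 0, 4: 0} for s in NTLX_SCALES}
    one_scale["effort"] = {1: 10, 2: 10, 3: 10, 4: 10}
    assert ntlx_composite(one_scale) == pytest.approx(10 / 6)


def test_ntlx_linear_ratings_give_midpoint_auc():
    scores = {s: {1: 4.0, 2: 8.0, 3: 12.0, 4: 16.0} for s in NTLX_SCALES}
    assert ntlx_composite(scores) == pytest.approx(10.0)


def test_ntlx_missing_scale_is_an_explicit_error():
    scores = {s: {1: 5, 2: 6} for s in NTLX_SCALES[:-1]}
    with pytest.raises(KeyError, match="frustration"):
        ntlx_composite(scores)
    bad = {s: {1: 25, 2: 5} for s in NTLX_SCALES}
    with pytest.raises(ValueError, match="outside"):
        ntlx_composite(bad)


# -- amount effect ----------------------------------------------------------


def test_identical_curves_give_zero_difference_and_na_p():
    pairs = [
        (curve({2: 0.8, 3: 0.6, 4: 0.4}, pid=i, base=1.0),
         curve({2: 0.8, 3: 0.6, 4: 0.4}, pid=i, base=5.0))
        for i in range(6)
    ]
    out = amount_effect(pairs)
    assert out["mean_difference"] == pytest.approx(0.0)
    assert np.isnan(out["wilcoxon_p"])


def test_decrement_worked_example():
    """Mean discounted value of $3.07 on a $5 base is a $1.93 decrement."""
    pairs = [
        (curve({2: 0.70, 3: 0.60, 4: 0.50}, pid=i, base=1.0),
         curve({2: 0.72, 3: 3.07 / 5, 4: 0.52}, pid=i, base=5.0))
        for i in range(4)
    ]
    out = amount_effect(pairs)
    per3 = out["per_condition"][3]
    assert per3["mean_discounted_value"][5.0] == pytest.approx(3.07)
    assert per3["decrement"][5.0] == pytest.approx(1.93)
    assert per3["mean_discounted_value"][1.0] == pytest.approx(0.60)
    assert per3["decrement"][1.0] == pytest.approx(0.40)


def test_amount_sensitive_agents_show_larger_auc_at_larger_base():
    from coged.agents import AgentParams, make_agent

    rng_seeds = range(12)
    aucs = {1.0: [], 5.0: []}
    for s in rng_seeds:
        params = AgentParams(kappa=0.25, gamma=0.4, tau=0.0, seed=s)
        for base in (1.0, 5.0):
            pts = {
                n: run_titration(make_agent(params), n, base).indifference_amount / base
                for n in (2, 3, 4)
            }
            aucs[base].append(discount_auc(curve(pts, base=base)).auc)
    assert np.mean(aucs[5.0]) > np.mean(aucs[1.0])


def test_unpaired_participants_are_dropped_with_warning():
    import pandas as pd

    df = pd.DataFrame(
        {
            "participant_id": ["a"] * 6 + ["b"] * 3,
            "domain": "effort",
            "base_amount": [1.0] * 3 + [5.0] * 3 + [1.0] * 3,
            "condition": [2, 3, 4] * 3,
            "sv": [0.9, 0.7, 0.5, 0.95, 0.8, 0.6, 0.9, 0.7, 0.5],
        }
    )
    with pytest.warns(UserWarning, match="lacks one base amount"):
        out = amount_effect(df)
    assert out["n_pairs"] == 1
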
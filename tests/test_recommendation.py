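import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fertiopt import FittedModelSet, recommend, recommend_for_cycle
from fertiopt.recommendation_engine import recommend_batch


def test_worked_example():
    rec = recommend(p_day5=0.9, yield_p=0.40, B=4.0, icsi=False, n_retrieved=15)
    assert rec.recommended_n == 10
    assert rec.predicted_day == "day5"
    assert rec.reason == "ratio_lt_retrieved"
    assert not rec.expose_all


def brute_force_n(B, p, m, k):
    """Smallest integer n with n >= (B / p) * m * k, found by linear scan."""
    target = (B / p) * m * k
    n = 1
    while n < target:
        n += 1
    return n


def test_ceiling_matches_brute_force_search():
    rng = np.random.default_rng(0)
    for _ in range(10_000):
        B = rng.uniform(0.2, 12.0)
        p = rng.uniform(0.05, 1.0)
        icsi = bool(rng.integers(2))
        k = int(rng.integers(1, 4))
        rec = recommend(p_day5=1.0, yield_p=p, B=B, icsi=icsi,
                        n_retrieved=10_000, desired_children=k)
        m = 0.70 if icsi else 1.0
        assert rec.recommended_n == brute_force_n(B, p, m, k)


def test_day3_branch_exposes_all():
    rec = recommend(p_day5=0.5, yield_p=None, B=None, icsi=True, n_retrieved=7)
    assert rec.predicted_day == "day3"
    assert rec.recommended_n == 7
    assert rec.expose_all
    assert rec.reason == "predicted_day3"


def test_threshold_tie_classifies_day5():
    rec = recommend(p_day5=0.75, yield_p=0.4, B=4.0, icsi=False, n_retrieved=15)
    assert rec.predicted_day == "day5"


def test_cap_at_retrieved():
    rec = recommend(p_day5=0.9, yield_p=0.2, B=5.0, icsi=False, n_retrieved=6)
    assert rec.recommended_n == 6
    assert rec.expose_all
    assert rec.reason == "ratio_ge_retrieved"


def test_desired_children_multiplies():
    one = recommend(p_day5=0.9, yield_p=0.4, B=4.0, icsi=False, n_retrieved=100)
    two = recommend(p_day5=0.9, yield_p=0.4, B=4.0, icsi=False, n_retrieved=100,
                    desired_children=2)
    assert one.recommended_n == 10
    assert two.recommended_n == 20


@pytest.mark.parametrize("kwargs", [
    dict(p_day5=-0.1, yield_p=0.4, B=4.0, icsi=False, n_retrieved=10),
    dict(p_day5=0.9, yield_p=0.0, B=4.0, icsi=False, n_retrieved=10),
    dict(p_day5=0.9, yield_p=0.4, B=0.0, icsi=False, n_retrieved=10),
    dict(p_day5=0.9, yield_p=0.4, B=4.0, icsi=False, n_retrieved=0),
    dict(p_day5=0.9, yield_p=None, B=None, icsi=False, n_retrieved=10),
    dict(p_day5=0.9, yield_p=0.4, B=4.0, icsi=False, n_retrieved=10,
         desired_children=0),
])
def test_invalid_inputs_raise(kwargs):
    with pytest.raises(ValueError):
        recommend(**kwargs)


@settings(max_examples=300, deadline=None)
@given(
    B=st.floats(0.1, 20.0),
    p=st.floats(0.01, 1.0),
    icsi=st.booleans(),
    n_ret=st.integers(1, 60),
)
def test_recommendation_invariants(B, p, icsi, n_ret):
    rec = recommend(p_day5=0.9, yield_p=p, B=B, icsi=icsi, n_retrieved=n_ret)
    assert 1 <= rec.recommended_n <= n_ret
    # monotone in B
    more = recommend(p_day5=0.9, yield_p=p, B=B + 1.0, icsi=icsi, n_retrieved=n_ret)
    assert more.recommended_n >= rec.recommended_n
    # antitone in the yield proportion
    if p <= 0.5:
        better = recommend(p_day5=0.9, yield_p=min(2 * p, 1.0), B=B, icsi=icsi,
                           n_retrieved=n_ret)
        assert better.recommended_n <= rec.recommended_n
    # ICSI never recommends more than conventional insemination
    conv = recommend(p_day5=0.9, yield_p=p, B=B, icsi=False, n_retrieved=n_ret)
    if icsi:
        assert rec.recommended_n <= conv.recommended_n


def test_batch_matches_scalar(fits, eligible):
    cycles = eligible.retrievals.head(300)
    batch = recommend_batch(fits, cycles)
    for idx in cycles.index[:40]:
        rec = recommend_for_cycle(fits, cycles.loc[idx])
        row = batch.loc[idx]
        assert rec.recommended_n == row["recommended_n"]
        assert rec.reason == row["reason"]
        assert rec.predicted_day == row["predicted_day"]


def test_batch_order_invariance(fits, eligible):
    cycles = eligible.retrievals.head(200)
    shuffled = cycles.sample(frac=1.0, random_state=1)
    a = recommend_batch(fits, cycles)
    b = recommend_batch(fits, shuffled).sort_index()
    pd.testing.assert_frame_equal(a, b)


def test_fitted_model_set_roundtrip(tmp_path, fits, eligible):
    fits.save(tmp_path)
    back = FittedModelSet.load(tmp_path)
    cycles = eligible.retrievals.head(200)
    pd.testing.assert_frame_equal(recommend_batch(fits, cycles),
                                  recommend_batch(back, cycles))


def test_ratio_uses_maturity_before_ceiling():
    # B=3, p=0.5 -> 6 raw; ICSI: 6 * 0.7 = 4.2 -> ceil 5 (not ceil(6)*0.7)
    rec = recommend(p_day5=0.9, yield_p=0.5, B=3.0, icsi=True, n_retrieved=50)
    assert rec.recommended_n == 5
    assert rec.raw_ratio == pytest.approx(6.0)
    assert math.ceil(rec.raw_ratio * rec.maturity_factor) == 5
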
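"""Catastrophic payment measures: worked examples, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from finprot.catastrophic import (
    DEFAULT_THRESHOLDS,
    Threshold,
    catastrophic_table,
    concentration_index,
    fractional_rank,
    head_count,
    oop_share,
    overshoot,
    rank_weighted_measures,
)
from finprot.errors import InputError, UndefinedIndexError

from conftest import make_dataset, oracle_concentration_index, random_dataset

SHARES = np.array([0.02, 0.08, 0.12, 0.30, 0.05])


# --- budget shares ---------------------------------------------------------

def test_oop_share_both_denominators():
    ds = make_dataset([100.0, 100.0], [50.0, 50.0], [10.0, 0.0])
    assert oop_share(ds, "total_expenditure").tolist() == [0.10, 0.0]
    assert oop_share(ds, "capacity_to_pay").tolist() == [0.20, 0.0]


def test_oop_share_clamps_when_oop_exceeds_nonfood_budget():
    # food + OOP > total is not excluded by validation; the capacity share
    # would exceed 1 and is clamped with a warning
    ds = make_dataset([100.0], [60.0], [50.0])
    with pytest.warns(UserWarning, match="clamped"):
        share = oop_share(ds, "capacity_to_pay")
    assert share.tolist() == [1.0]


def test_zero_capacity_with_zero_oop_gives_zero_share():
    ds = make_dataset([100.0, 100.0], [100.0, 50.0], [0.0, 10.0])
    assert oop_share(ds, "capacity_to_pay").tolist() == [0.0, 0.2]


# --- head count and overshoot ---------------------------------------------

def test_head_count_manual_enumeration():
    assert head_count(SHARES, 0.10) == pytest.approx(0.40)  # exactly 2 of 5 exceed


def test_head_count_zero_when_nothing_exceeds():
    assert head_count([0.01, 0.05, 0.10], 0.10) == 0.0  # strict ">": 0.10 not counted


def test_head_count_weighted():
    # weights 1,1,1,1,6: only the last share (0.05) is below z=0.10 -> H = 4/10...
    shares = [0.2, 0.2, 0.2, 0.2, 0.05]
    assert head_count(shares, 0.10, weights=[1, 1, 1, 1, 6]) == pytest.approx(0.4)


def test_overshoot_manual_arithmetic():
    o_i, o, mpo = overshoot(SHARES, 0.10)
    assert o_i == pytest.approx([0.0, 0.0, 0.02, 0.20, 0.0])
    assert o == pytest.approx(0.044)
    assert mpo == pytest.approx(0.11)


def test_overshoot_at_exact_threshold_is_zero():
    o_i, o, mpo = overshoot([0.10, 0.10, 0.10], 0.10)
    assert o == 0.0
    assert mpo is None  # H = 0 -> MPO undefined, not 0


def test_empty_input_rejected():
    with pytest.raises(InputError):
        head_count([], 0.1)
    with pytest.raises(InputError):
        overshoot([], 0.1)


# --- fractional ranks and concentration index ------------------------------

def test_fractional_rank_equal_weights_textbook():
    r = fractional_rank([10.0, 20.0, 30.0, 40.0, 50.0])
    assert r.tolist() == [0.1, 0.3, 0.5, 0.7, 0.9]


def test_fractional_rank_follows_sort_not_input_order():
    r = fractional_rank([50.0, 10.0, 30.0])
    assert r.tolist() == [5 / 6, 1 / 6, 0.5]


def test_fractional_rank_ties_stable_vs_average():
    unit = fractional_rank([1.0, 1.0, 2.0], tie_rank="unit")
    assert unit.tolist() == [1 / 6, 0.5, 5 / 6]  # input order breaks the tie
    avg = fractional_rank([1.0, 1.0, 2.0], tie_rank="average")
    assert avg.tolist() == [1 / 3, 1 / 3, 5 / 6]  # tied pair shares its midpoint


def test_concentration_index_hand_computed_value():
    # outcome (0,0,0,1,1) on ascending ranks r=(0.1,...,0.9): mean 0.4,
    # population covariance 0.12 -> C = 2*0.12/0.4 = 0.6
    y = [0.0, 0.0, 0.0, 1.0, 1.0]
    ranks = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert concentration_index(y, ranks) == pytest.approx(0.6)
    assert oracle_concentration_index(y, ranks) == pytest.approx(0.6)


def test_concentration_index_constant_outcome_is_zero():
    assert concentration_index([2.0] * 6, list(range(6))) == pytest.approx(0.0)


def test_concentration_index_antisymmetric_in_rank():
    rng = np.random.default_rng(5)
    y = rng.random(30)
    v = rng.random(30)
    c = concentration_index(y, v)
    assert concentration_index(y, -v) == pytest.approx(-c)


def test_concentration_index_zero_mean_outcome_rejected():
    with pytest.raises(UndefinedIndexError):
        concentration_index([0.0, 0.0], [1.0, 2.0])
    with pytest.raises(InputError):
        concentration_index([1.0], [1.0])


@settings(max_examples=60, derandomize=True)
@given(
    y=hnp.arrays(np.float64, st.integers(2, 40),
                 elements=st.floats(0, 100, allow_nan=False)),
    data=st.data(),
)
def test_concentration_index_matches_definitional_double_sum(y, data):
    n = y.size
    v = data.draw(hnp.arrays(np.float64, n, elements=st.floats(0, 1000)))
    w = data.draw(hnp.arrays(np.float64, n, elements=st.floats(0.1, 10)))
    if y.sum() == 0:
        return
    assert concentration_index(y, v, w) == pytest.approx(
        oracle_concentration_index(y, v, w), abs=1e-10
    )


def test_concentration_index_bounded_for_nonnegative_outcomes():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = rng.integers(2, 30)
        y = rng.exponential(1.0, n)
        v = rng.random(n)
        w = rng.uniform(0.1, 5.0, n)
        assert abs(concentration_index(y, v, w)) <= 1.0 + 1e-12


# --- rank-weighted measures -------------------------------------------------

def test_rank_weighted_measures_printed_table_value():
    # H = 5.5 %, C_E = 0.09 -> H_w = 5.005 %, printed as 5.0 %
    h_w, _ = rank_weighted_measures(0.055, 0.0, 0.09, 0.0)
    assert h_w == pytest.approx(0.05005)
    assert round(100 * h_w, 1) == 5.0


def test_rank_weighted_neutral_and_propoor():
    assert rank_weighted_measures(0.3, 0.1, 0.0, 0.0) == (0.3, 0.1)
    h_w, _ = rank_weighted_measures(0.3, 0.1, -0.2, 0.0)
    assert h_w > 0.3  # pro-poor concentration inflates the weighted count


def test_rank_weighted_identity_direct_sum(rng):
    """H(1-C_E) must equal the direct weighted mean with weights 2(1-r)."""
    for n in (7, 50, 300):
        ds = random_dataset(rng, n)
        w = rng.uniform(0.5, 3.0, n)
        shares = oop_share(ds, "total_expenditure")
        e = (shares > 0.1).astype(float)
        if e.sum() == 0:
            continue
        r = fractional_rank(ds.total_expenditure, w)
        direct = np.sum(w * 2 * (1 - r) * e) / np.sum(w)
        c_e = concentration_index(e, ds.total_expenditure, w)
        h = head_count(shares, 0.1, w)
        assert h * (1 - c_e) == pytest.approx(direct, abs=1e-10)


# --- full table -------------------------------------------------------------

def test_table_monotone_in_threshold(rng):
    ds = random_dataset(rng, 500)
    for denom in ("total_expenditure", "capacity_to_pay"):
        zs = [0.05, 0.10, 0.15, 0.25, 0.40]
        res = catastrophic_table(ds, [Threshold(z, denom) for z in zs])
        hs = [r.head_count for r in res]
        os_ = [r.mean_overshoot for r in res]
        assert all(a >= b for a, b in zip(hs, hs[1:]))
        assert all(a >= b for a, b in zip(os_, os_[1:]))


def test_capacity_head_count_dominates_total(rng):
    ds = random_dataset(rng, 400)
    s_tot = oop_share(ds, "total_expenditure")
    s_ctp = oop_share(ds, "capacity_to_pay")
    assert np.all(s_ctp >= s_tot)
    for z in (0.05, 0.15, 0.25):
        assert head_count(s_ctp, z) >= head_count(s_tot, z)


def test_mpo_decomposition(rng):
    ds = random_dataset(rng, 300)
    for res in catastrophic_table(ds, DEFAULT_THRESHOLDS):
        if res.head_count > 0:
            assert res.mpo * res.head_count == pytest.approx(
                res.mean_overshoot, abs=1e-12
            )
        else:
            assert res.mpo is None


def test_rich_only_burden_gives_positive_ci_and_deflated_count():
    # only the richest household exceeds the threshold
    total = [100.0, 200.0, 300.0, 400.0, 1000.0]
    oop = [0.0, 0.0, 0.0, 0.0, 500.0]
    ds = make_dataset(total, [20.0] * 5, oop)
    (res,) = catastrophic_table(ds, [Threshold(0.25, "total_expenditure")])
    assert res.head_count == pytest.approx(0.2)
    assert res.ci_incidence == pytest.approx(0.8)  # 2*cov((0,0,0,0,1), r)/0.2
    assert res.weighted_head_count < res.head_count


def test_empty_threshold_list_rejected(rng):
    with pytest.raises(InputError):
        catastrophic_table(random_dataset(rng, 10), [])


def test_result_invariants_on_random_data(rng):
    ds = random_dataset(rng, 600)
    for res in catastrophic_table(ds, DEFAULT_THRESHOLDS):
        z = res.threshold.z
        assert 0.0 <= res.head_count <= 1.0
        assert 0.0 <= res.mean_overshoot <= res.head_count * (1 - z) + 1e-15
        assert res.weighted_head_count == pytest.approx(
            res.head_count * (1 - res.ci_incidence)
        )
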
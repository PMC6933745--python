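"""Fractional ranks, concentration index/curve, robust inference, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import healthbia as hb


def test_fractional_rank_midpoint_construction():
    assert np.allclose(hb.fractional_rank([1, 2], [1, 1]), [0.25, 0.75])
    assert np.allclose(hb.fractional_rank([1, 2], [1, 3]), [0.125, 0.625])
    assert np.allclose(hb.fractional_rank([7], [2]), [0.5])


def test_fractional_rank_stable_tie_breaking():
    ranks = hb.fractional_rank([5, 5, 5, 5], [1, 1, 1, 1])
    assert np.allclose(ranks, [0.125, 0.375, 0.625, 0.875])


def test_concentration_index_hand_cases():
    r = hb.fractional_rank([1, 2], [1, 1])
    assert hb.concentration_index([3, 3], r, [1, 1]) == 0.0
    assert np.isclose(hb.concentration_index([0, 1], r, [1, 1]), 0.5)
    assert np.isclose(hb.concentration_index([1, 0], r, [1, 1]), -0.5)


def test_concentration_index_undefined_at_zero_mean():
    r = hb.fractional_rank([1, 2], [1, 1])
    assert np.isnan(hb.concentration_index([0.0, 0.0], r, [1, 1]))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_regression_slope_equals_covariance_index(seed):
    rng = np.random.default_rng(seed)
    n = 50
    h = rng.gamma(2.0, 100.0, n)
    w = rng.uniform(0.5, 2.0, n)
    mpce = rng.lognormal(9, 0.5, n)
    ranks = hb.fractional_rank(mpce, w)
    C = hb.concentration_index(h, ranks, w)
    slope, se, p = hb.convenient_regression_se(h, ranks, w)
    assert slope == pytest.approx(C, abs=1e-10)
    assert se > 0 and 0 <= p <= 1


def test_regression_constant_h_gives_null():
    r = hb.fractional_rank([1, 2, 3], [1, 1, 1])
    slope, se, p = hb.convenient_regression_se([5, 5, 5], r, [1, 1, 1])
    assert slope == pytest.approx(0.0, abs=1e-9)
    assert p > 0.9


def test_curve_constant_h_is_diagonal():
    curve = hb.concentration_curve([2, 2, 2, 2], [1, 2, 3, 4], [1, 1, 1, 1])
    assert np.allclose(curve[:, 0], curve[:, 1])


def test_curve_all_subsidy_on_richest():
    curve = hb.concentration_curve([0, 1], [1, 2], [1, 1])
    assert np.allclose(curve, [[0, 0], [0.5, 0], [1, 1]])


def test_curve_through_published_cumulated_shares():
    """Four class-level records carrying the rural inpatient benefit
    shares reported in the national study (9.90/27.84/26.63/35.63%),
    equal class population shares: the curve passes through the
    cumulated points."""
    shares = [0.0990, 0.2784, 0.2663, 0.3563]
    curve = hb.concentration_curve(shares, [1, 2, 3, 4], [1, 1, 1, 1])
    expected = [(0.25, 0.0990), (0.50, 0.3774), (0.75, 0.6437), (1.0, 1.0)]
    for p, L in expected:
        i = np.argmin(np.abs(curve[:, 0] - p))
        assert curve[i, 1] == pytest.approx(L, abs=1e-6)


def test_index_equals_twice_trapezoid_area():
    rng = np.random.default_rng(42)
    for n in (10, 100, 1000):
        h = rng.gamma(2.0, 10.0, n)
        w = rng.uniform(0.5, 2.0, n)
        mpce = rng.lognormal(9, 0.4, n)
        C = hb.concentration_index(h, hb.fractional_rank(mpce, w), w)
        area = hb.curve_area_index(hb.concentration_curve(h, mpce, w))
        assert C == pytest.approx(area, abs=1e-6)


def test_grouped_index_hand_cases():
    eq = [0.25, 0.25, 0.25, 0.25]
    assert hb.grouped_concentration_index(eq, eq) == pytest.approx(0.0)
    assert hb.grouped_concentration_index(
        [0, 0, 0, 1], eq
    ) == pytest.approx(0.75)
    assert hb.grouped_concentration_index(
        [1, 0, 0, 0], eq
    ) == pytest.approx(-0.75)
    with pytest.raises(ValueError):
        hb.grouped_concentration_index([0.5, 0.5, 0.5, 0.5], eq)
    with pytest.raises(ValueError):
        hb.grouped_concentration_index([-0.2, 0.4, 0.4, 0.4], eq)


def test_micro_index_equals_grouped_for_group_constant_subsidy():
    """Contiguous classes with constant within-class subsidy: the micro
    covariance form reduces to the grouped formula."""
    rng = np.random.default_rng(3)
    sizes = [40, 30, 20, 10]
    h_levels = [5.0, 1.0, 3.0, 8.0]
    mpce = np.concatenate(
        [i + rng.uniform(0, 0.5, s) for i, s in enumerate(sizes)]
    )
    h = np.concatenate(
        [np.full(s, lvl) for s, lvl in zip(sizes, h_levels)]
    )
    w = np.ones(mpce.size)
    C_micro = hb.concentration_index(h, hb.fractional_rank(mpce, w), w)
    pop = np.array(sizes) / sum(sizes)
    benefit = np.array(sizes) * np.array(h_levels)
    C_grouped = hb.grouped_concentration_index(benefit / benefit.sum(), pop)
    assert C_micro == pytest.approx(C_grouped, abs=1e-10)


@given(st.integers(0, 10_000), st.floats(0.1, 50.0))
@settings(deadline=None, derandomize=True, max_examples=25)
def test_scale_and_weight_invariance(seed, k):
    rng = np.random.default_rng(seed)
    n = 30
    h = rng.gamma(1.5, 5.0, n)
    w = rng.uniform(0.5, 2.0, n)
    mpce = rng.lognormal(9, 0.4, n)
    ranks = hb.fractional_rank(mpce, w)
    C = hb.concentration_index(h, ranks, w)
    assert hb.concentration_index(k * h, ranks, w) == pytest.approx(
        C, abs=1e-9
    )
    assert hb.concentration_index(
        h, hb.fractional_rank(mpce, k * w), k * w
    ) == pytest.approx(C, abs=1e-9)
    assert abs(C) <= 1.0 + 1e-12


def test_sign_law_matches_curve_side():
    rng = np.random.default_rng(8)
    n = 200
    mpce = np.sort(rng.lognormal(9, 0.4, n))
    w = np.ones(n)
    pro_poor = np.linspace(2, 0.1, n)  # benefit falls with rank
    curve = hb.concentration_curve(pro_poor, mpce, w)
    inner = curve[1:-1]
    assert (inner[:, 1] >= inner[:, 0]).all()  # curve above diagonal
    C = hb.concentration_index(
        pro_poor, hb.fractional_rank(mpce, w), w
    )
    assert C < 0
    pro_rich = pro_poor[::-1]
    C2 = hb.concentration_index(
        pro_rich, hb.fractional_rank(mpce, w), w
    )
    assert C2 > 0


def _bootstrap_frame(n_hh=40, per_hh=2, seed=0, constant_h=False):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_hh):
        mpce = float(rng.lognormal(9, 0.4))
        for j in range(per_hh):
            rows.append(
                {"household_id": f"H{i}", "mpce": mpce,
                 "h": 1.0 if constant_h else float(rng.gamma(2.0, 10.0)),
                 "weight": float(rng.uniform(0.5, 2.0))}
            )
    return pd.DataFrame(rows)


def test_bootstrap_band_deterministic_and_contains_estimate():
    df = _bootstrap_frame()
    grid, lo, hi = hb.bootstrap_band(df, B=200, seed=5)
    grid2, lo2, hi2 = hb.bootstrap_band(df, B=200, seed=5)
    assert np.array_equal(lo, lo2) and np.array_equal(hi, hi2)
    curve = hb.concentration_curve(df["h"], df["mpce"], df["weight"])
    est = hb.curve_on_grid(curve, grid)
    assert (lo <= est + 1e-9).all() and (est <= hi + 1e-9).all()


def test_bootstrap_band_zero_width_for_constant_h():
    df = _bootstrap_frame(constant_h=True)
    # constant h per unit weight: every resampled curve hits the diagonal
    grid, lo, hi = hb.bootstrap_band(df, B=100, seed=1)
    # width collapses only where weights are equal; use equal weights
    df["weight"] = 1.0
    grid, lo, hi = hb.bootstrap_band(df, B=100, seed=1)
    assert np.allclose(hi - lo, 0.0, atol=5e-3)


def test_bootstrap_refuses_fewer_than_ten_households():
    df = _bootstrap_frame(n_hh=5)
    with pytest.raises(ValueError, match="households"):
        hb.bootstrap_band(df, B=100, seed=0)


def test_compute_concentration_curve_invariants(small_pipeline):
    subs = small_pipeline["results"]["subsidies"]["IP"]
    res = hb.compute_concentration(subs.assign(h=subs["gamma"]), h_col="h")
    curve = res.curve
    assert tuple(curve[0]) == (0.0, 0.0)
    assert tuple(curve[-1]) == (1.0, 1.0)
    assert (np.diff(curve[:, 0]) >= -1e-12).all()
    assert (np.diff(curve[:, 1]) >= -1e-12).all()
    assert abs(res.index) <= 1.0
    assert res.n_obs == len(subs)


def test_estimator_power_on_planted_pro_rich_gradient():
    """With a negative private-choice gradient (the rich use public
    facilities more), the benefit distribution is planted pro-rich: the
    estimated full-sample index is positive and significant in nearly
    all seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(1, n_seeds + 1):
        cfg = hb.SimConfig(
            seed=seed, private_gradient=-0.4
        ).with_target_ip_episodes(5000)
        dataset, truth = hb.generate(cfg)
        cls = hb.build_mpce_classification(dataset)
        ip, op = hb.select_elderly_ncd(
            dataset, cls, hb.default_ailment_map()
        )
        results = hb.run_benefit_incidence(ip, op)
        subs = results["subsidies"]["IP"].copy()
        rates = dict(zip(
            results["benefit"]["IP"]["combine"]["mpce_class"],
            results["benefit"]["IP"]["combine"]["delta"],
        ))
        subs["h"] = subs["mpce_class"].map(rates) * subs["gamma"]
        res = hb.compute_concentration(subs, h_col="h")
        hits += (res.index > 0) and (res.p_value < 0.05)
    assert hits >= 18
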
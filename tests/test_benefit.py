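"""Modal private-cost proxy, net subsidy, utilization rates, benefit shares."""

import numpy as np
import pandas as pd
import pytest

import healthbia as hb
from conftest import brute_force_pi, make_inpatient


def _private(rows):
    """Private-episode frame with stratum labels: rows of
    (eid, state, sector, cls, stay, total, weight)."""
    out = make_inpatient([
        (eid, "P1", "20", "private", stay, total, 0.0, 0.0, 0.0, w)
        for eid, _, _, _, stay, total, w in rows
    ])
    out["state"] = [r[1] for r in rows]
    out["sector"] = [r[2] for r in rows]
    out["mpce_class"] = [r[3] for r in rows]
    return out


@pytest.mark.parametrize(
    "service,days,expected",
    [
        ("IP", 3, "1-3"), ("IP", 4, "4-7"), ("IP", 1, "1-3"),
        ("IP", 400, "15+"), ("OP", 14, "0-14"), ("OP", 0, "0-14"),
        ("OP", 15, "15-30"), ("OP", 91, "91+"),
    ],
)
def test_duration_band_boundaries(service, days, expected):
    assert hb.duration_band(service, days)[0] == expected


def test_duration_band_rejects_invalid_days():
    with pytest.raises(ValueError):
        hb.duration_band("OP", -1)
    with pytest.raises(ValueError):
        hb.duration_band("IP", 0)


def test_binned_mode_unique_and_tied_bins():
    # unique mode bin [500, 600): weighted mean of members = 500
    assert hb.binned_mode([500, 500, 700], [1, 1, 1], 100) == 500
    # tie between bins [100,200) and [900,1000): lower bin wins
    assert hb.binned_mode([100, 900], [1, 1], 100) == 100
    # weights can flip the winning bin
    assert hb.binned_mode([100, 900], [1, 3], 100) == 900


def test_modal_cost_full_support_stratum():
    rows = [(f"E{i}", "S01", "rural", "P", 2, v, 1.0)
            for i, v in enumerate([500, 500, 520, 700, 900])]
    tbl = hb.modal_private_cost(
        _private(rows), "IP", hb.BiaConfig(ip_bin=100)
    )
    cost, n, level = tbl.resolve("S01", "rural", "P", "1-3")
    assert level == "full"
    assert n == 5
    assert np.isclose(cost, (500 + 500 + 520) / 3)


def test_modal_cost_sparse_stratum_pools_durations():
    rows = [(f"A{i}", "S01", "rural", "P", 2, 500.0, 1.0) for i in range(2)]
    rows += [(f"B{i}", "S01", "rural", "P", 5, 900.0, 1.0) for i in range(4)]
    tbl = hb.modal_private_cost(
        _private(rows), "IP", hb.BiaConfig(ip_bin=100)
    )
    # band 1-3 has n=2 < 5 -> pooled over durations: 6 values, mode bin
    # [900, 1000) with weighted count 4 beats [500, 600) with 2
    cost, n, level = tbl.resolve("S01", "rural", "P", "1-3")
    assert level == "drop_duration"
    assert n == 6
    assert cost == 900.0
    # band 4-7 alone is also sparse (n=4): same pooled value
    cost2, _, level2 = tbl.resolve("S01", "rural", "P", "4-7")
    assert (cost2, level2) == (900.0, "drop_duration")


def test_modal_cost_ladder_reaches_global():
    rows = [(f"E{i}", "S01", "rural", "P", 2, 500.0, 1.0) for i in range(3)]
    tbl = hb.modal_private_cost(_private(rows), "IP", hb.BiaConfig())
    cost, n, level = tbl.resolve("S09", "urban", "R", "15+")
    assert level == "global"
    assert n == 3
    assert cost == 500.0


def test_modal_cost_requires_private_episodes():
    with pytest.raises(ValueError, match="private"):
        hb.modal_private_cost(_private([]), "IP")


def _public_episode(total, state="S01", sector="rural", cls="P", stay=2,
                    weight=1.0, eid="E1"):
    df = make_inpatient(
        [(eid, "P1", "20", "public", stay, total, 0.0, 0.0, 0.0, weight)]
    )
    df["state"], df["sector"], df["mpce_class"] = state, sector, cls
    return df


def _modal_table_at(value):
    rows = [(f"M{i}", "S01", "rural", "P", 2, float(value), 1.0)
            for i in range(5)]
    return hb.modal_private_cost(_private(rows), "IP", hb.BiaConfig())


def test_net_subsidy_subtraction_and_clamp():
    tbl = _modal_table_at(20000)
    out = hb.net_subsidy(_public_episode(4374.0), tbl)
    assert np.isclose(out["gamma"].iloc[0], 15626.0)
    assert not out["clamped"].iloc[0]

    tbl_low = _modal_table_at(1000)
    clamped = hb.net_subsidy(_public_episode(2500.0), tbl_low, clamp=True)
    assert clamped["gamma"].iloc[0] == 0.0
    assert clamped["clamped"].sum() == 1

    literal = hb.net_subsidy(_public_episode(2500.0), tbl_low, clamp=False)
    assert np.isclose(literal["gamma"].iloc[0], -1500.0)


def test_utilization_rates_weighted_shares():
    def frame(pairs):
        df = pd.DataFrame(pairs, columns=["mpce_class", "weight"])
        return df

    r = hb.utilization_rates(frame([(c, 1.0) for c in hb.CLASS_ORDER]))
    assert np.allclose(r, 0.25)
    r = hb.utilization_rates(
        frame([("P", 1), ("P", 1), ("LM", 1), ("UM", 1)])
    )
    assert list(r) == [0.5, 0.25, 0.25, 0.0]
    r = hb.utilization_rates(frame([("LM", 2.0)]))
    assert list(r) == [0.0, 1.0, 0.0, 0.0]
    with pytest.raises(ValueError):
        hb.utilization_rates(frame([]))
    assert np.isclose(sum(r), 1.0)


def _subsidy_frame(rows):
    df = pd.DataFrame(
        rows, columns=["mpce_class", "weight", "gamma"]
    )
    df["clamped"] = False
    return df


def test_benefit_shares_symmetric_case():
    rows = [(c, 1.0, 50.0) for c in hb.CLASS_ORDER]
    out = hb.benefit_incidence_shares(_subsidy_frame(rows))
    assert np.allclose(out["share_pct"], 25.0)


def test_benefit_shares_delta_weighting_hand_case():
    """Class subsidy sums all equal 100 but utilization rates
    (0.4, 0.3, 0.2, 0.1): the printed formula makes shares proportional
    to delta_j, i.e. (40, 30, 20, 10)."""
    rows = []
    rows += [("P", 1.0, 25.0)] * 4
    rows += [("LM", 1.0, 100.0 / 3)] * 3
    rows += [("UM", 1.0, 50.0)] * 2
    rows += [("R", 1.0, 100.0)] * 1
    out = hb.benefit_incidence_shares(_subsidy_frame(rows))
    assert np.allclose(out["delta"], [0.4, 0.3, 0.2, 0.1])
    assert np.allclose(out["share_pct"], [40, 30, 20, 10])
    # unweighted sensitivity variant: equal sums -> equal shares
    out2 = hb.benefit_incidence_shares(
        _subsidy_frame(rows), weighted_rates=False
    )
    assert np.allclose(out2["share_pct"], 25.0)


def test_benefit_shares_single_class_holds_all():
    rows = [("UM", 2.0, 10.0), ("P", 1.0, 0.0)]
    out = hb.benefit_incidence_shares(_subsidy_frame(rows))
    assert out.set_index("mpce_class").loc["UM", "share_pct"] == 100.0


def test_benefit_shares_zero_total_is_missing():
    rows = [(c, 1.0, 0.0) for c in hb.CLASS_ORDER]
    out = hb.benefit_incidence_shares(_subsidy_frame(rows))
    assert out["share_pct"].isna().all()


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pipeline_pi_matches_brute_force_formula(seed):
    """Oracle equivalence on a random fixture of <= 30 episodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 30))
    rows = [
        (rng.choice(hb.CLASS_ORDER), float(rng.uniform(0.5, 3)),
         float(rng.uniform(0, 5000)))
        for _ in range(n)
    ]
    frame = _subsidy_frame(rows)
    out = hb.benefit_incidence_shares(frame).set_index("mpce_class")
    brute = brute_force_pi(frame)
    for cls in hb.CLASS_ORDER:
        assert out.loc[cls, "pi"] == pytest.approx(brute[cls], rel=1e-12)


def test_full_run_shares_sum_and_clamp_bounds(small_pipeline):
    results = small_pipeline["results"]
    long = hb.benefit_table_long(results)
    sums = long.groupby(["service", "sector"])["share_pct"].sum()
    assert np.allclose(sums, 100.0, atol=0.01)
    for service, subs in results["subsidies"].items():
        assert (subs["gamma"] >= 0).all()
    assert ((long["share_pct"] >= 0) & (long["share_pct"] <= 100)).all()
    deltas = long.groupby(["service", "sector"])["delta"].sum()
    assert np.allclose(deltas, 1.0)


def test_modal_table_has_pooling_provenance(small_pipeline):
    tbl = small_pipeline["results"]["modal_costs"]["IP"].table
    assert set(tbl["pooling_level"]) <= set(
        ("full", "drop_duration", "drop_class", "drop_state", "global")
    )
    assert (tbl["modal_cost"] >= 0).all()
    full = tbl[tbl["pooling_level"] == "full"]
    assert (full["n_private"] >= 5).all()
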
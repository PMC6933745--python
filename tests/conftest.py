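"""Shared fixtures: hand-built micro-fixtures and cached synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import healthbia as hb


def make_households(rows):
    cols = ["household_id", "state", "sector", "total_monthly_expenditure",
            "household_size", "weight"]
    return pd.DataFrame(rows, columns=cols)


def make_individuals(rows):
    cols = ["person_id", "household_id", "age", "sex", "weight"]
    return pd.DataFrame(rows, columns=cols)


def make_inpatient(rows):
    cols = ["episode_id", "person_id", "ailment_code", "facility",
            "stay_days", "oope_medicine", "oope_other_medical",
            "oope_transport", "oope_other_nonmedical", "weight"]
    return pd.DataFrame(rows, columns=cols)


def make_outpatient(rows):
    cols = ["spell_id", "person_id", "visit_ailment_codes",
            "ailment_duration_days", "facility", "oope_medicine",
            "oope_other_medical", "oope_transport", "oope_other_nonmedical",
            "weight"]
    return pd.DataFrame(rows, columns=cols)


def make_dataset(households=None, individuals=None, inpatient=None,
                 outpatient=None) -> hb.SurveyDataset:
    return hb.SurveyDataset(
        households=make_households(households or []),
        individuals=make_individuals(individuals or []),
        inpatient=make_inpatient(inpatient or []),
        outpatient=make_outpatient(outpatient or []),
    )


@pytest.fixture
def tiny_dataset() -> hb.SurveyDataset:
    """One rural cell with 4 households spanning the four classes.

    MPCE values are 10000/20000/30000/40000 (size-1 households), so the
    weighted quartile cutpoints are exactly (10000, 20000, 30000) and the
    four elderly persons land in P, LM, UM, R respectively.
    """
    households = [
        (f"H{i}", "S01", "rural", 10000.0 * i, 1, 1.0) for i in range(1, 5)
    ]
    individuals = [
        (f"P{i}", f"H{i}", 60 + i, "F", 1.0) for i in range(1, 5)
    ] + [("P9", "H1", 30, "M", 1.0)]
    inpatient = [
        ("E1", "P1", "20", "public", 2, 100.0, 50.0, 20.0, 5.0, 1.0),
        ("E2", "P2", "20", "private", 5, 500.0, 100.0, 0.0, 0.0, 1.0),
        ("E3", "P3", "05", "public", 3, 40.0, 0.0, 0.0, 0.0, 1.0),
        ("E4", "P4", "21", "public", 9, 10.0, 10.0, 10.0, 10.0, 1.0),
    ]
    outpatient = [
        ("V1", "P1", "20;21", 10, "public", 50.0, 10.0, 5.0, 0.0, 1.0),
        ("V2", "P2", "20;05", 30, "public", 80.0, 0.0, 0.0, 0.0, 1.0),
        ("V3", "P3", "22", 100, "private", 200.0, 40.0, 10.0, 0.0, 1.0),
    ]
    return make_dataset(households, individuals, inpatient, outpatient)


@pytest.fixture(scope="session")
def small_sim():
    """One midsize generated dataset reused across read-only tests."""
    cfg = hb.SimConfig(seed=11, households_per_state_sector=400)
    dataset, truth = hb.generate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Classification + elderly-NCD selection + benefit results for it."""
    _, dataset, truth = small_sim
    classification = hb.build_mpce_classification(dataset)
    amap = hb.default_ailment_map()
    ip, op = hb.select_elderly_ncd(dataset, classification, amap)
    results = hb.run_benefit_incidence(ip, op)
    return {
        "dataset": dataset, "truth": truth,
        "classification": classification, "ailment_map": amap,
        "ip": ip, "op": op, "results": results,
    }


def brute_force_pi(subsidies: pd.DataFrame) -> dict:
    """Independent evaluation of pi_j = delta_j * sum_{k in j} w_k gamma_k.

    Loops record by record, no vectorization shared with the pipeline.
    """
    total_w = sum(w for w in subsidies["weight"])
    delta = {}
    for cls in hb.CLASS_ORDER:
        delta[cls] = sum(
            float(r.weight) for r in subsidies.itertuples()
            if r.mpce_class == cls
        ) / total_w
    pi = {}
    for cls in hb.CLASS_ORDER:
        acc = 0.0
        for r in subsidies.itertuples():
            if r.mpce_class == cls:
                acc += float(r.weight) * float(r.gamma)
        pi[cls] = delta[cls] * acc
    return pi
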
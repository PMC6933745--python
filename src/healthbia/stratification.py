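"""Living-standard classes, ailment grouping and the analysis population.

Households are ranked by *equivalized* monthly per-capita expenditure
(MPCE): total monthly expenditure divided by the square root of household
size (the OECD square-root equivalence scale).  Within every
(state, sector) cell the weighted quartiles of MPCE split households into
four classes — Poorest (P), Lower Middle (LM), Upper Middle (UM) and
Richest (R) — which individuals inherit from their household.  Quartiles
are computed per cell because the cost of living differs markedly across
states and between the rural and urban sector.

Ailments are partitioned into communicable (CD), noncommunicable (NCD)
and other/residual (OD) groups, following the three-way grouping of the
World Development Report 1993.  The analysis population is individuals
aged 60 and above with NCD care: every hospitalization episode whose
ailment is NCD, and every outpatient spell in which *all* visits are for
NCDs (the outpatient expenditure is pooled over the visits of a spell, so
a spell with any non-NCD visit cannot be attributed to NCD care and is
excluded entirely).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import parse_visit_codes
from .schema import AILMENT_GROUPS, CLASS_ORDER, SurveyDataset

ELDERLY_AGE = 60


def equivalized_mpce(total_expenditure, household_size):
    """OECD square-root scale: T / sqrt(N).  Vectorized."""
    size = np.asarray(household_size, dtype=float)
    if np.any(size < 1):
        raise ValueError("household_size must be >= 1")
    return np.asarray(total_expenditure, dtype=float) / np.sqrt(size)


def weighted_quantile(values, weights, probs):
    """Left-continuous inverse of the weighted empirical CDF.

    Returns, for each probability p, the lowest value whose cumulative
    weight share is >= p.  No interpolation: reproducible on discrete
    survey data.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty cell")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order]) / weights.sum()
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    # first index where cumulative share >= p (tolerate fp rounding at 1.0)
    idx = np.searchsorted(cum, np.minimum(probs, cum[-1]) - 1e-12, side="left")
    return v[np.minimum(idx, v.size - 1)]


@dataclass
class MpceClassification:
    """Per-(state, sector) quartile cutpoints and per-unit class labels.

    ``cutpoints`` has one row per usable (state, sector) cell with columns
    q25 <= q50 <= q75 and the household count; ``households`` and
    ``individuals`` carry ``mpce`` and ``mpce_class`` per unit.
    """

    cutpoints: pd.DataFrame
    households: pd.DataFrame
    individuals: pd.DataFrame
    warnings: list = field(default_factory=list)


def mpce_cutpoints(households: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Weighted quartile cutpoints of equivalized MPCE per (state, sector).

    Computed over households (one record each) with household survey
    weights.  Cells with fewer than 4 households are flagged unusable and
    omitted with a warning.
    """
    warnings = []
    rows = []
    mpce = equivalized_mpce(
        households["total_monthly_expenditure"], households["household_size"]
    )
    df = households.assign(_mpce=mpce)
    for (state, sector), cell in df.groupby(["state", "sector"], sort=True):
        if len(cell) < 4:
            warnings.append(
                f"cell ({state}, {sector}): only {len(cell)} households; "
                f"omitted"
            )
            continue
        q25, q50, q75 = weighted_quantile(
            cell["_mpce"], cell["weight"], [0.25, 0.50, 0.75]
        )
        rows.append(
            {"state": state, "sector": sector, "q25": q25, "q50": q50,
             "q75": q75, "n_households": len(cell)}
        )
    return pd.DataFrame(rows), warnings


def assign_class(mpce, q25, q50, q75):
    """Class label from cutpoints; ties go down (mpce == q25 -> P)."""
    mpce = np.asarray(mpce, dtype=float)
    out = np.full(mpce.shape, "R", dtype=object)
    out[mpce <= np.asarray(q75)] = "UM"
    out[mpce <= np.asarray(q50)] = "LM"
    out[mpce <= np.asarray(q25)] = "P"
    return out


def build_mpce_classification(dataset: SurveyDataset) -> MpceClassification:
    """Classify households by per-cell MPCE quartiles; members inherit.

    Households in a (state, sector) cell without cutpoints are excluded
    with a warning count (class label missing).
    """
    cutpoints, warnings = mpce_cutpoints(dataset.households)
    hh = dataset.households.copy()
    hh["mpce"] = equivalized_mpce(
        hh["total_monthly_expenditure"], hh["household_size"]
    )
    if cutpoints.empty:
        raise ValueError("no usable (state, sector) cell for classification")
    hh = hh.merge(cutpoints, on=["state", "sector"], how="left")
    covered = hh["q25"].notna()
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        warnings.append(
            f"{n_uncovered} household(s) in uncovered cells excluded from "
            f"classification"
        )
    hh["mpce_class"] = pd.array([None] * len(hh), dtype=object)
    hh.loc[covered, "mpce_class"] = assign_class(
        hh.loc[covered, "mpce"], hh.loc[covered, "q25"],
        hh.loc[covered, "q50"], hh.loc[covered, "q75"]
    )
    hh_out = hh[["household_id", "state", "sector", "mpce", "mpce_class"]]
    ind = dataset.individuals.merge(
        hh_out, on="household_id", how="left", suffixes=("", "_hh")
    )
    ind_out = ind[
        ["person_id", "household_id", "age", "state", "sector", "mpce",
         "mpce_class"]
    ]
    return MpceClassification(
        cutpoints=cutpoints, households=hh_out, individuals=ind_out,
        warnings=warnings,
    )


class AilmentMap:
    """Total mapping from ailment code to {CD, NCD, OD}.

    Built from a ``{group: [codes]}`` partition; overlapping entries are a
    configuration error.  Codes outside the configured universe fall back
    to OD (the residual group for conditions that are neither clearly
    communicable nor noncommunicable) with a warning.
    """

    def __init__(self, code_to_group: dict[str, str]):
        bad = {g for g in code_to_group.values()} - set(AILMENT_GROUPS)
        if bad:
            raise ValueError(f"unknown ailment groups: {sorted(bad)}")
        self._map = dict(code_to_group)
        self.unmapped_warnings = 0

    @classmethod
    def from_groups(cls, groups: dict[str, list[str]]) -> "AilmentMap":
        seen: dict[str, str] = {}
        for group, codes in groups.items():
            for code in codes:
                if code in seen:
                    raise ValueError(
                        f"ailment code {code!r} mapped to both {seen[code]} "
                        f"and {group}: groups must partition the code universe"
                    )
                seen[code] = group
        return cls(seen)

    @classmethod
    def from_json(cls, path) -> "AilmentMap":
        return cls.from_groups(json.loads(Path(path).read_text()))

    def classify(self, code: str) -> str:
        group = self._map.get(code)
        if group is None:
            self.unmapped_warnings += 1
            return "OD"
        return group

    def classify_series(self, codes: pd.Series) -> pd.Series:
        mapped = codes.map(self._map)
        self.unmapped_warnings += int(mapped.isna().sum())
        return mapped.fillna("OD")

    def codes(self) -> dict[str, str]:
        return dict(self._map)


def classify_ailment(code: str, ailment_map: AilmentMap) -> str:
    return ailment_map.classify(code)


def default_ailment_map() -> AilmentMap:
    """Illustrative NSS-71-style grouping of two-digit ailment codes.

    The survey's own code list is not normative here; edit or replace via
    :meth:`AilmentMap.from_json` to match a concrete extract.
    """
    cd = [f"{c:02d}" for c in range(1, 11)]       # infections, fevers, TB ...
    ncd = [f"{c:02d}" for c in range(20, 40)]     # cardiovascular, diabetes,
                                                  # cancers, respiratory ...
    od = [f"{c:02d}" for c in range(90, 100)]     # injuries, childbirth, ill-
                                                  # defined conditions
    return AilmentMap.from_groups({"CD": cd, "NCD": ncd, "OD": od})


def select_elderly_ncd(
    dataset: SurveyDataset,
    classification: MpceClassification,
    ailment_map: AilmentMap,
    age_min: int = ELDERLY_AGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Episodes/spells of the elderly-NCD analysis population.

    Returns ``(ip, op)``: hospitalization episodes of individuals aged
    ``age_min`` and above whose ailment is NCD, and outpatient spells of
    such individuals in which *every* visit's ailment maps to NCD.  Both
    frames are joined with the person's state, sector, MPCE value and
    class.  Idempotent: re-selecting from the returned sets is a no-op.
    """
    persons = classification.individuals
    elderly = persons[persons["age"] >= age_min]

    keys = ["person_id", "household_id", "state", "sector", "mpce",
            "mpce_class"]
    ip = dataset.inpatient.merge(elderly[keys], on="person_id", how="inner")
    ip = ip[ailment_map.classify_series(ip["ailment_code"]) == "NCD"]

    op = dataset.outpatient.merge(elderly[keys], on="person_id", how="inner")
    if len(op):
        codes = parse_visit_codes(op["visit_ailment_codes"])
        all_ncd = codes.map(
            lambda cs: bool(cs)
            and all(ailment_map.classify(c) == "NCD" for c in cs)
        )
        op = op[np.asarray(all_ncd, dtype=bool)]
    return ip.reset_index(drop=True), op.reset_index(drop=True)
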
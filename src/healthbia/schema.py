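"""Canonical data model for the survey-style microdata consumed by the pipeline.

The pipeline works on four linked tables mirroring the structure of the
Indian National Sample Survey health rounds (household roster, individual
roster, one record per hospitalization episode, one record per outpatient
spell).  Column names here are *canonical*: a column-mapping block in the
load configuration adapts any concrete survey extract to them.

Units and conventions
---------------------
* Currency values are nonnegative reals in INR (no deflation or PPP
  adjustment is applied anywhere in the pipeline).
* ``weight`` is a survey multiplier (> 0), i.e. the number of population
  units a record represents.
* ``sector`` is ``"rural"`` or ``"urban"``; ``facility`` is ``"public"``
  or ``"private"``.
* An outpatient spell pools the out-of-pocket expenditure of *all* visits
  in the 15-day recall window; ``visit_ailment_codes`` holds one ailment
  code per visit (serialized as a ``;``-separated string in CSV files).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SECTORS = ("rural", "urban")
FACILITIES = ("public", "private")
SERVICES = ("IP", "OP")

#: MPCE class labels in ascending order of living standard.
CLASS_ORDER = ("P", "LM", "UM", "R")

#: Ailment groups: communicable, noncommunicable, other/residual.
AILMENT_GROUPS = ("CD", "NCD", "OD")

OOPE_COMPONENTS = (
    "oope_medicine",
    "oope_other_medical",
    "oope_transport",
    "oope_other_nonmedical",
)

HOUSEHOLD_COLUMNS = (
    "household_id",
    "state",
    "sector",
    "total_monthly_expenditure",
    "household_size",
    "weight",
)

INDIVIDUAL_COLUMNS = (
    "person_id",
    "household_id",
    "age",
    "sex",
    "weight",
)

INPATIENT_COLUMNS = (
    "episode_id",
    "person_id",
    "ailment_code",
    "facility",
    "stay_days",
    *OOPE_COMPONENTS,
    "weight",
)

OUTPATIENT_COLUMNS = (
    "spell_id",
    "person_id",
    "visit_ailment_codes",
    "ailment_duration_days",
    "facility",
    *OOPE_COMPONENTS,
    "weight",
)

TABLE_COLUMNS = {
    "households": HOUSEHOLD_COLUMNS,
    "individuals": INDIVIDUAL_COLUMNS,
    "inpatient": INPATIENT_COLUMNS,
    "outpatient": OUTPATIENT_COLUMNS,
}

TABLE_ID_COLUMN = {
    "households": "household_id",
    "individuals": "person_id",
    "inpatient": "episode_id",
    "outpatient": "spell_id",
}


@dataclass
class SurveyDataset:
    """Linked household / individual / inpatient / outpatient tables."""

    households: pd.DataFrame
    individuals: pd.DataFrame
    inpatient: pd.DataFrame
    outpatient: pd.DataFrame
    #: issues recorded at load time (e.g. unparseable numeric cells),
    #: surfaced by :func:`healthbia.io.validate`.
    load_errors: list = field(default_factory=list)
    load_warnings: list = field(default_factory=list)

    def tables(self):
        return {
            "households": self.households,
            "individuals": self.individuals,
            "inpatient": self.inpatient,
            "outpatient": self.outpatient,
        }

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            households=self.households.copy(),
            individuals=self.individuals.copy(),
            inpatient=self.inpatient.copy(),
            outpatient=self.outpatient.copy(),
            load_errors=list(self.load_errors),
            load_warnings=list(self.load_warnings),
        )

    def equals(self, other: "SurveyDataset") -> bool:
        return all(
            self.tables()[name].reset_index(drop=True).equals(
                other.tables()[name].reset_index(drop=True)
            )
            for name in self.tables()
        )


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    record_id: str
    rule: str
    message: str = ""


@dataclass
class ValidationReport:
    """Record-level invariant violations found in a :class:`SurveyDataset`.

    Violations are data, not exceptions: an empty ``errors`` list means the
    dataset satisfies every type invariant.
    """

    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [
            f"{name}: {n} records" for name, n in sorted(self.counts.items())
        ]
        lines.append(f"errors: {len(self.errors)}, warnings: {len(self.warnings)}")
        return "\n".join(lines)
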
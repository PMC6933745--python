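"""Reading, validating and writing the pipeline's tables.

``load_survey`` reads four delimited files into the canonical schema, via a
column-mapping block so that arbitrary survey extracts can be adapted
without renaming files by hand.  ``validate`` checks every type invariant
and reports violations record by record.  ``write_table``/``read_table``
round-trip result tables through CSV or JSON.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .schema import (
    FACILITIES,
    OOPE_COMPONENTS,
    SECTORS,
    TABLE_COLUMNS,
    TABLE_ID_COLUMN,
    SurveyDataset,
    ValidationIssue,
    ValidationReport,
)

_STRING_COLUMNS = {
    "household_id",
    "person_id",
    "episode_id",
    "spell_id",
    "state",
    "sector",
    "sex",
    "ailment_code",
    "facility",
    "visit_ailment_codes",
}

_NUMERIC_COLUMNS = {
    "total_monthly_expenditure",
    "household_size",
    "weight",
    "age",
    "stay_days",
    "ailment_duration_days",
    *OOPE_COMPONENTS,
}


class PathsConfig(BaseModel):
    """Input files plus the mapping from source columns to canonical fields.

    ``column_map[table]`` maps *source* column names to canonical names;
    canonical columns already present are used as-is.  ``state_recode``
    merges state codes (e.g. club small states/UTs into a pooled code)
    before any stratification.
    """

    households: Path
    individuals: Path
    inpatient: Path
    outpatient: Path
    column_map: dict[str, dict[str, str]] = Field(default_factory=dict)
    state_recode: dict[str, str] = Field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PathsConfig":
        path = Path(path)
        cfg = json.loads(path.read_text())
        for key in ("households", "individuals", "inpatient", "outpatient"):
            if key in cfg and not Path(cfg[key]).is_absolute():
                cfg[key] = str(path.parent / cfg[key])
        return cls(**cfg)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def load_survey(paths_config) -> SurveyDataset:
    """Read the four survey tables into the canonical schema.

    Missing files and unmappable required columns are fatal.  Unparseable
    numeric cells become NaN and are reported as record-level errors by
    :func:`validate`.  Missing OOPE component columns or blank OOPE cells
    are treated as zero with a warning (survey extracts commonly blank
    zero cells).  Unknown columns are preserved but ignored; row order is
    preserved.
    """
    if isinstance(paths_config, (str, Path)):
        paths_config = PathsConfig.from_json(paths_config)
    elif isinstance(paths_config, dict):
        paths_config = PathsConfig(**paths_config)

    frames: dict[str, pd.DataFrame] = {}
    load_errors: list[ValidationIssue] = []
    load_warnings: list[str] = []

    for table, required in TABLE_COLUMNS.items():
        path = getattr(paths_config, table)
        if not Path(path).exists():
            raise FileNotFoundError(f"{table} file not found: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        mapping = paths_config.column_map.get(table, {})
        rename = {src: dst for src, dst in mapping.items() if src in df.columns}
        df = df.rename(columns=rename)

        for col in required:
            if col not in df.columns:
                if col in OOPE_COMPONENTS:
                    df[col] = "0"
                    load_warnings.append(
                        f"{table}: missing OOPE column {col!r} filled with 0"
                    )
                else:
                    raise ValueError(
                        f"{table}: required column {col!r} absent and not "
                        f"supplied by column_map"
                    )

        id_col = TABLE_ID_COLUMN[table]
        for col in required:
            if col in _NUMERIC_COLUMNS:
                raw = df[col].astype(str).str.strip()
                blank = raw == ""
                if col in OOPE_COMPONENTS and blank.any():
                    raw = raw.where(~blank, "0")
                    load_warnings.append(
                        f"{table}: {int(blank.sum())} blank {col} cell(s) "
                        f"treated as 0"
                    )
                parsed = pd.to_numeric(raw, errors="coerce")
                bad = parsed.isna() & (raw != "")
                for rid in df.loc[bad, id_col]:
                    load_errors.append(
                        ValidationIssue(
                            table, str(rid), f"unparseable_numeric:{col}"
                        )
                    )
                df[col] = parsed
        if paths_config.state_recode and "state" in df.columns:
            df["state"] = df["state"].replace(paths_config.state_recode)
        frames[table] = df
        _log(f"loaded {table}: {len(df)} rows from {path}")

    return SurveyDataset(
        households=frames["households"],
        individuals=frames["individuals"],
        inpatient=frames["inpatient"],
        outpatient=frames["outpatient"],
        load_errors=load_errors,
        load_warnings=load_warnings,
    )


def _flag(errors, df, mask, table, rule, id_col):
    for rid in df.loc[mask.fillna(False).astype(bool), id_col]:
        errors.append(ValidationIssue(table, str(rid), rule))


def validate(dataset: SurveyDataset) -> ValidationReport:
    """Check every type invariant; the dataset is not mutated.

    Every violation appears exactly once, keyed by record id and rule name.
    """
    errors: list[ValidationIssue] = list(dataset.load_errors)
    warnings: list[str] = list(dataset.load_warnings)

    hh = dataset.households
    ind = dataset.individuals
    ip = dataset.inpatient
    op = dataset.outpatient

    _flag(errors, hh, hh["total_monthly_expenditure"] < 0, "households",
          "total_monthly_expenditure>=0", "household_id")
    _flag(errors, hh, ~(hh["household_size"] >= 1), "households",
          "household_size>=1", "household_id")
    _flag(errors, hh, ~(hh["weight"] > 0), "households", "weight>0",
          "household_id")
    _flag(errors, hh, (hh["state"].astype(str).str.strip() == ""),
          "households", "state_nonmissing", "household_id")
    _flag(errors, hh, ~hh["sector"].isin(SECTORS), "households",
          "sector_in_rural_urban", "household_id")

    known_hh = set(hh["household_id"])
    _flag(errors, ind, ~ind["household_id"].isin(known_hh), "individuals",
          "household_id_resolves", "person_id")
    _flag(errors, ind, ~(ind["age"] >= 0), "individuals", "age>=0",
          "person_id")
    _flag(errors, ind, ~(ind["weight"] > 0), "individuals", "weight>0",
          "person_id")

    known_persons = set(ind["person_id"])
    for table, df, id_col in (
        ("inpatient", ip, "episode_id"),
        ("outpatient", op, "spell_id"),
    ):
        _flag(errors, df, ~df["person_id"].isin(known_persons), table,
              "person_id_resolves", id_col)
        _flag(errors, df, ~df["facility"].isin(FACILITIES), table,
              "facility_in_public_private", id_col)
        _flag(errors, df, ~(df["weight"] > 0), table, "weight>0", id_col)
        for col in OOPE_COMPONENTS:
            _flag(errors, df, df[col] < 0, table, f"{col}>=0", id_col)

    _flag(errors, ip, ~(ip["stay_days"] >= 1), "inpatient", "stay_days>=1",
          "episode_id")
    _flag(errors, op, ~(op["ailment_duration_days"] >= 0), "outpatient",
          "ailment_duration_days>=0", "spell_id")
    n_visits = (
        op["visit_ailment_codes"].astype(str).str.strip().str.split(";").map(
            lambda v: sum(1 for x in v if x)
        )
    )
    _flag(errors, op, ~(n_visits >= 1), "outpatient", "at_least_one_visit",
          "spell_id")

    counts = {name: len(df) for name, df in dataset.tables().items()}
    return ValidationReport(errors=errors, warnings=warnings, counts=counts)


def parse_visit_codes(series: pd.Series) -> pd.Series:
    """Split ``;``-separated visit ailment codes into lists."""
    return series.astype(str).map(
        lambda s: [c for c in s.strip().split(";") if c]
    )


def write_table(table, path, format: str = "csv") -> None:
    """Write a result table; re-reading reproduces values to full precision.

    DataFrames go to CSV (default) or JSON (records orient); objects with a
    ``to_json`` method (e.g. ``ConcentrationResult``) go to JSON.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(table, "to_json") and not isinstance(table, pd.DataFrame):
        path.write_text(table.to_json())
        return
    if not isinstance(table, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(table)!r}")
    if format == "csv":
        table.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        path.write_text(
            table.to_json(orient="records", double_precision=15)
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_table(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        return pd.read_csv(path)
    return pd.DataFrame(json.loads(path.read_text()))
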
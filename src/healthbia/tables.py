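"""Survey-weighted utilization-share and mean-OOPE tables.

Utilization is counted per hospitalization episode / outpatient spell (the
spell is the outpatient unit because its expenditure is pooled across
visits).  All shares and means are weighted by the survey multipliers, so
doubling every weight changes nothing; the "combine" sector pools the
rural and urban records rather than averaging the two columns.
"""

from __future__ import annotations

import sys

import numpy as np
import pandas as pd

from .schema import AILMENT_GROUPS, CLASS_ORDER


def oope_components(df: pd.DataFrame) -> pd.DataFrame:
    """Medicine / medical / total out-of-pocket expenditure per record.

    medicine  = spending on medicines;
    medical   = medicine + other medical care (fees, diagnostics, ...);
    total     = medical + transport + other non-medical spending (food,
                escorts, lodging ...).
    """
    out = df.copy()
    out["medicine"] = df["oope_medicine"].astype(float)
    out["medical"] = out["medicine"] + df["oope_other_medical"].astype(float)
    out["total"] = (
        out["medical"]
        + df["oope_transport"].astype(float)
        + df["oope_other_nonmedical"].astype(float)
    )
    return out


def _sector_frames(df: pd.DataFrame):
    yield "rural", df[df["sector"] == "rural"]
    yield "urban", df[df["sector"] == "urban"]
    yield "combine", df


def _weighted_shares(df, key, universe):
    """100 * (sum of weights per key value) / (sum of weights overall)."""
    denom = df["weight"].sum()
    if denom <= 0:
        return {k: np.nan for k in universe}
    grouped = df.groupby(key)["weight"].sum()
    return {k: 100.0 * grouped.get(k, 0.0) / denom for k in universe}


def utilization_share_table(
    elderly_ip: pd.DataFrame,
    elderly_op: pd.DataFrame,
    ailment_map,
) -> pd.DataFrame:
    """Three-panel utilization table (long format).

    ``elderly_ip``/``elderly_op`` are *all* episodes/spells of the elderly,
    joined with MPCE class; panels restrict the universe:

    * ``ailment_group`` — CD/NCD/OD shares among all elderly episodes;
    * ``ncd_by_class`` — class shares among elderly NCD episodes;
    * ``ncd_public_by_class`` — class shares among elderly NCD episodes in
      public facilities.

    Within each (panel, service, sector) the shares sum to 100 whenever
    the universe is nonempty; an empty universe yields missing values with
    a warning on stderr.
    """
    ip = elderly_ip.copy()
    op = elderly_op.copy()
    ip["ailment_group"] = ailment_map.classify_series(ip["ailment_code"])
    if len(op) and "ailment_group" not in op.columns:
        from .io import parse_visit_codes

        codes = parse_visit_codes(op["visit_ailment_codes"])
        # group of a spell: the group of its visits if uniform, else OD
        def spell_group(cs):
            gs = {ailment_map.classify(c) for c in cs}
            return gs.pop() if len(gs) == 1 else "OD"

        op["ailment_group"] = codes.map(spell_group)
    elif "ailment_group" not in op.columns:
        op["ailment_group"] = pd.Series(dtype=object)

    rows = []
    for service, df in (("IP", ip), ("OP", op)):
        for sector, sdf in _sector_frames(df):
            panels = [
                ("ailment_group", sdf, "ailment_group", AILMENT_GROUPS),
                ("ncd_by_class", sdf[sdf["ailment_group"] == "NCD"],
                 "mpce_class", CLASS_ORDER),
                ("ncd_public_by_class",
                 sdf[(sdf["ailment_group"] == "NCD")
                     & (sdf["facility"] == "public")],
                 "mpce_class", CLASS_ORDER),
            ]
            for panel, pdf, key, universe in panels:
                if pdf["weight"].sum() <= 0:
                    print(
                        f"utilization: empty universe for panel={panel} "
                        f"service={service} sector={sector}",
                        file=sys.stderr,
                    )
                shares = _weighted_shares(pdf, key, universe)
                for group, share in shares.items():
                    rows.append(
                        {"panel": panel, "service": service,
                         "sector": sector, "group": group,
                         "share_pct": share}
                    )
    return pd.DataFrame(rows)


def mean_oope_table(
    ip_ncd: pd.DataFrame, op_ncd: pd.DataFrame
) -> pd.DataFrame:
    """Weighted mean medicine/medical/total OOPE by class, sector, facility.

    Input frames are the elderly-NCD selections with ``mpce_class`` and
    ``sector``; the ``All`` row pools the classes.  Empty cells are
    missing values, not zeros.
    """
    rows = []
    for service, df in (("IP", ip_ncd), ("OP", op_ncd)):
        comp = oope_components(df)
        for sector, sdf in _sector_frames(comp):
            for facility in ("public", "private"):
                fdf = sdf[sdf["facility"] == facility]
                for cls in (*CLASS_ORDER, "All"):
                    cdf = fdf if cls == "All" else fdf[
                        fdf["mpce_class"] == cls
                    ]
                    w = cdf["weight"].astype(float)
                    wsum = w.sum()
                    for component in ("medicine", "medical", "total"):
                        mean = (
                            float((cdf[component] * w).sum() / wsum)
                            if wsum > 0 else np.nan
                        )
                        rows.append(
                            {"service": service, "sector": sector,
                             "facility": facility, "mpce_class": cls,
                             "component": component, "mean_oope": mean}
                        )
    return pd.DataFrame(rows)
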
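"""Benefit-incidence analysis of the public subsidy for NCD care.

The public provision cost of an episode is proxied by the *modal*
out-of-pocket expenditure observed in private facilities within the same
stratum — state x sector x MPCE class x duration band (length of hospital
stay for inpatient care, total ailment duration for outpatient care) —
so that differences in severity, quality and regional price level are
held fixed as far as the data allow.  The net subsidy of a public-facility
episode is

    gamma_k = modal private OOPE(stratum of k) - total OOPE of k,

clamped at zero by default (a subsidy cannot be negative under the
proxy's own logic; the clamp count is reported and a toggle preserves the
literal subtraction).  With delta_j the weighted share of class j in all
public-facility episodes for the service, the benefit enjoyed by class j
is

    pi_j = delta_j * sum_{k in class j} w_k * gamma_k,

and the benefit-incidence share is 100 * pi_j / sum_j pi_j.  The
delta-weighting makes the shares differ from plain subsidy sums (it
counts utilization twice); an unweighted variant is available as a
sensitivity option, never as the default.

The mode of a continuous cost variable is defined by fixed-width binning:
values fall into half-open bins [m*w, (m+1)*w); the modal cost is the
weighted mean of the values in the weighted-count-maximizing bin, ties
broken toward the lower bin.  Strata with fewer private episodes than
``min_cell_size`` fall back along the pooling ladder
drop_duration -> drop_class -> drop_state -> global, and the level used
is recorded per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .schema import CLASS_ORDER
from .tables import oope_components

#: duration-band edges (inclusive), upper bound None = open top band
DEFAULT_IP_BANDS = ((1, 3), (4, 7), (8, 14), (15, None))
DEFAULT_OP_BANDS = ((0, 14), (15, 30), (31, 90), (91, None))

POOLING_LEVELS = ("full", "drop_duration", "drop_class", "drop_state",
                  "global")


class BiaConfig(BaseModel):
    """Tunables of the benefit-incidence computation.

    ``ip_bin``/``op_bin`` are the cost-bin widths (INR) used to locate the
    modal private OOPE; ``min_cell_size`` is the minimum number of private
    episodes a stratum needs before the pooling ladder is invoked.
    """

    min_cell_size: int = 5
    ip_bin: float = 500.0
    op_bin: float = 50.0
    clamp: bool = True
    weighted_rates: bool = True
    ip_bands: tuple = DEFAULT_IP_BANDS
    op_bands: tuple = DEFAULT_OP_BANDS


def band_label(lo, hi) -> str:
    return f"{lo}-{hi}" if hi is not None else f"{lo}+"


def duration_band(service: str, days, bands=None) -> np.ndarray:
    """Duration band label(s) for stay days (IP) or ailment duration (OP)."""
    if bands is None:
        bands = DEFAULT_IP_BANDS if service == "IP" else DEFAULT_OP_BANDS
    days = np.atleast_1d(np.asarray(days, dtype=float))
    if np.any(days < 0) or (service == "IP" and np.any(days < 1)):
        raise ValueError("invalid duration for service " + service)
    out = np.empty(days.shape, dtype=object)
    out[:] = None
    for lo, hi in bands:
        mask = days >= lo if hi is None else (days >= lo) & (days <= hi)
        out[np.asarray(mask) & (out == None)] = band_label(lo, hi)  # noqa: E711
    if np.any(out == None):  # noqa: E711
        raise ValueError("duration not covered by band configuration")
    return out


def binned_mode(values, weights, bin_width: float) -> float:
    """Weighted mean of the weighted-count-maximizing cost bin.

    Bins are [m*w, (m+1)*w); ties between bins go to the lower bin.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("binned_mode of empty set")
    bins = np.floor(values / bin_width).astype(np.int64)
    order = np.argsort(bins, kind="stable")
    uniq, start = np.unique(bins[order], return_index=True)
    wsums = np.add.reduceat(weights[order], start)
    best = uniq[np.argmax(wsums)]  # argmax returns first max: lower bin wins
    member = bins == best
    return float(
        np.average(values[member], weights=weights[member])
    )


@dataclass
class ModalCostTable:
    """Modal private cost per stratum with pooling provenance.

    ``table`` has one row per stratum key with the resolved modal cost,
    the private-episode count at the resolved level and the
    ``pooling_level`` used.  ``levels`` holds the raw per-level lookups.
    """

    service: str
    bin_width: float
    min_cell_size: int
    table: pd.DataFrame
    levels: dict = field(default_factory=dict)

    _KEY = {
        "full": ["state", "sector", "mpce_class", "duration_band"],
        "drop_duration": ["state", "sector", "mpce_class"],
        "drop_class": ["state", "sector"],
        "drop_state": ["sector"],
        "global": [],
    }

    def resolve(self, state, sector, mpce_class, duration_band):
        """(modal_cost, n, pooling_level) via the fallback ladder."""
        key_values = {
            "state": state, "sector": sector, "mpce_class": mpce_class,
            "duration_band": duration_band,
        }
        for level in POOLING_LEVELS:
            key = tuple(key_values[c] for c in self._KEY[level])
            hit = self.levels[level].get(key)
            if hit is None:
                continue
            cost, n = hit
            if n >= self.min_cell_size or level == "global":
                return cost, n, level
        raise RuntimeError("global pooling level missing")  # unreachable


def modal_private_cost(
    private: pd.DataFrame, service: str, config: BiaConfig | None = None
) -> ModalCostTable:
    """Build the modal private-cost table for one service.

    ``private`` must carry state, sector, mpce_class, duration column
    (``stay_days`` or ``ailment_duration_days``), OOPE components and
    weights.  Fatal if there are no private episodes at all: the cost
    proxy is undefined without a private comparator.
    """
    config = config or BiaConfig()
    if len(private) == 0:
        raise ValueError(
            f"no private {service} episodes: modal-cost proxy undefined"
        )
    bin_width = config.ip_bin if service == "IP" else config.op_bin
    bands = config.ip_bands if service == "IP" else config.op_bands
    dur_col = "stay_days" if service == "IP" else "ailment_duration_days"

    df = oope_components(private)
    df = df.assign(duration_band=duration_band(service, df[dur_col], bands))

    levels = {}
    for level, key_cols in ModalCostTable._KEY.items():
        lookup = {}
        groups = (
            df.groupby(key_cols, sort=True)
            if key_cols else [((), df)]
        )
        for key, cell in groups:
            if key_cols and not isinstance(key, tuple):
                key = (key,)
            lookup[key] = (
                binned_mode(cell["total"], cell["weight"], bin_width),
                len(cell),
            )
        levels[level] = lookup

    rows = []
    full_keys = df[ModalCostTable._KEY["full"]].drop_duplicates()
    tbl = ModalCostTable(
        service=service, bin_width=bin_width,
        min_cell_size=config.min_cell_size, table=pd.DataFrame(),
        levels=levels,
    )
    for _, r in full_keys.iterrows():
        cost, n, level = tbl.resolve(
            r["state"], r["sector"], r["mpce_class"], r["duration_band"]
        )
        rows.append(
            {"service": service, "state": r["state"], "sector": r["sector"],
             "mpce_class": r["mpce_class"],
             "duration_band": r["duration_band"], "modal_cost": cost,
             "n_private": n, "pooling_level": level}
        )
    tbl.table = pd.DataFrame(rows).sort_values(
        ["state", "sector", "mpce_class", "duration_band"]
    ).reset_index(drop=True)
    return tbl


def net_subsidy(
    public: pd.DataFrame,
    modal_table: ModalCostTable,
    clamp: bool = True,
    bands=None,
) -> pd.DataFrame:
    """Per-episode net subsidy gamma for public-facility episodes.

    Adds columns ``modal_cost``, ``pooling_level``, ``gamma`` and
    ``clamped``.  With ``clamp`` (default) negative subsidies are floored
    at zero and counted; without it the literal subtraction is kept.
    """
    service = modal_table.service
    dur_col = "stay_days" if service == "IP" else "ailment_duration_days"
    df = oope_components(public)
    df = df.assign(duration_band=duration_band(service, df[dur_col], bands))

    resolved = [
        modal_table.resolve(s, sec, cls, band)
        for s, sec, cls, band in zip(
            df["state"], df["sector"], df["mpce_class"], df["duration_band"]
        )
    ]
    df["modal_cost"] = [r[0] for r in resolved]
    df["pooling_level"] = [r[2] for r in resolved]
    gamma = df["modal_cost"] - df["total"]
    df["clamped"] = gamma < 0
    df["gamma"] = np.maximum(gamma, 0.0) if clamp else gamma
    return df


def utilization_rates(public: pd.DataFrame) -> pd.Series:
    """delta_j: weighted share of class j in all public episodes.

    Sums to 1 over the four classes; fatal on an empty episode set.
    """
    if len(public) == 0:
        raise ValueError("utilization_rates of empty episode set")
    denom = public["weight"].sum()
    grouped = public.groupby("mpce_class")["weight"].sum()
    return pd.Series(
        {cls: grouped.get(cls, 0.0) / denom for cls in CLASS_ORDER},
        name="delta",
    )


def benefit_incidence_shares(
    subsidies: pd.DataFrame,
    rates: pd.Series | None = None,
    weighted_rates: bool = True,
) -> pd.DataFrame:
    """Class-wise benefit pi_j and percentage shares.

    ``subsidies`` is the output of :func:`net_subsidy` (public episodes
    with ``gamma``).  pi_j = delta_j * sum_{k in j} w_k gamma_k; with
    ``weighted_rates=False`` the delta factor is dropped (sensitivity
    variant).  Shares are missing (with a warning) when the total benefit
    is zero.
    """
    if rates is None:
        rates = utilization_rates(subsidies)
    rows = []
    for cls in CLASS_ORDER:
        cdf = subsidies[subsidies["mpce_class"] == cls]
        wgamma = float((cdf["gamma"] * cdf["weight"]).sum())
        delta = float(rates[cls])
        pi = delta * wgamma if weighted_rates else wgamma
        rows.append(
            {"mpce_class": cls, "delta": delta, "sum_weighted_gamma": wgamma,
             "pi": pi, "n_episodes": len(cdf),
             "n_clamped": int(cdf["clamped"].sum())}
        )
    out = pd.DataFrame(rows)
    total = out["pi"].sum()
    if total > 0:
        out["share_pct"] = 100.0 * out["pi"] / total
    else:
        import sys

        print("benefit incidence: total benefit is zero; shares undefined",
              file=sys.stderr)
        out["share_pct"] = np.nan
    return out


def run_benefit_incidence(
    elderly_ip: pd.DataFrame,
    elderly_op: pd.DataFrame,
    config: BiaConfig | None = None,
) -> dict:
    """Full benefit-incidence computation for both services and sectors.

    Inputs are the elderly-NCD inpatient episodes and outpatient spells
    (with state/sector/class labels).  For each service the modal-cost
    table is built from the private episodes of the *whole* sample (the
    strata already separate sectors); benefit tables are computed per
    sector and for the pooled "combine" sector.

    Returns a dict with per-service ``modal_costs``, per-service
    per-sector ``benefit`` tables and ``subsidies`` (episode-level frames
    used downstream by the concentration analysis).
    """
    config = config or BiaConfig()
    out: dict = {"benefit": {}, "modal_costs": {}, "subsidies": {}}
    for service, df in (("IP", elderly_ip), ("OP", elderly_op)):
        if len(df) == 0:
            continue
        bands = config.ip_bands if service == "IP" else config.op_bands
        private = df[df["facility"] == "private"]
        public = df[df["facility"] == "public"]
        modal = modal_private_cost(private, service, config)
        out["modal_costs"][service] = modal
        subs = net_subsidy(public, modal, clamp=config.clamp, bands=bands)
        out["subsidies"][service] = subs
        out["benefit"][service] = {}
        for sector in ("rural", "urban", "combine"):
            sdf = subs if sector == "combine" else subs[
                subs["sector"] == sector
            ]
            if len(sdf) == 0:
                continue
            out["benefit"][service][sector] = benefit_incidence_shares(
                sdf, weighted_rates=config.weighted_rates
            )
    return out


def benefit_table_long(results: dict) -> pd.DataFrame:
    """Flatten ``run_benefit_incidence`` output into one long DataFrame."""
    frames = []
    for service, sectors in results["benefit"].items():
        for sector, tbl in sectors.items():
            frames.append(tbl.assign(service=service, sector=sector))
    cols = ["service", "sector", "mpce_class", "delta", "sum_weighted_gamma",
            "pi", "share_pct", "n_episodes", "n_clamped"]
    return pd.concat(frames, ignore_index=True)[cols]
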
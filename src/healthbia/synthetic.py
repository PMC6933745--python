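"""Survey-like microdata generator with planted, known equity structure.

The generator emulates the *structure* of an NSS-style health round —
state x sector household frame, lognormal-like household expenditure,
survey multiplier weights, age-graded NCD morbidity, income-graded
facility choice, public out-of-pocket expenditure systematically below
private — without calibrating to any real survey's marginals.  Every
downstream stage of the pipeline therefore has a ground truth to recover:

* Private OOPE in each stratum is drawn from a *shifted lognormal
  re-parameterized by its mode*, so the stratum's true cost location is
  exactly the distribution's mode and modal-cost recovery is well posed.
* Public OOPE is a configured fraction of the stratum's cost location
  times multiplicative noise, so the planted per-episode net subsidy is
  ``max(location - public OOPE, 0)``.
* Facility choice is a logit in the household's MPCE quartile with
  log-odds gradient ``private_gradient`` (g): g > 0 means richer classes
  choose private care more, making public utilization pro-poor; g = 0
  plants no class gradient at all.
* Cost locations are class-flat and state-flat by default, so the planted
  equity structure is driven by the utilization gradient alone and the
  planted concentration index is ~0 when g = 0.  Class/state cost
  gradients can be switched on in the config.

Weights are drawn from a bounded positive distribution independent of
expenditure, so weighted and unweighted estimands differ detectably but
boundedly.  Multistage clustering is not simulated: records are
independent given their stratum (the concentration module's bootstrap
resamples households instead).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .benefit import DEFAULT_IP_BANDS, DEFAULT_OP_BANDS, duration_band
from .concentration import grouped_concentration_index
from .schema import CLASS_ORDER, SurveyDataset
from .stratification import (
    assign_class,
    default_ailment_map,
    equivalized_mpce,
    mpce_cutpoints,
)

_CLASS_INDEX = {cls: i for i, cls in enumerate(CLASS_ORDER)}


class SimConfig(BaseModel):
    """Study conditions of the simulated survey.

    Defaults emulate the published national survey round at reduced scale:
    ~66k households, ~8% elderly, mean household size 5, ~42% of elderly
    hospitalizations for NCDs, private OOPE well above public.  Currency
    is INR; locations are distribution modes, not means.
    """

    seed: int = 0
    n_states: int = 4
    households_per_state_sector: int = 5500
    # household economy
    #: log-location of *equivalized* MPCE per sector; household totals
    #: scale with sqrt(household size) around it
    log_mean_expenditure: dict[str, float] = Field(
        default_factory=lambda: {"rural": math.log(9000.0),
                                 "urban": math.log(14000.0)}
    )
    log_sd_expenditure: float = 0.55
    state_expenditure_shift: list[float] | None = None
    mean_household_size: float = 5.0
    weight_base: float = 100.0
    weight_low: float = 0.5
    weight_high: float = 2.0
    # demography and morbidity
    elderly_fraction: float = 0.082
    elderly_age_scale: float = 8.0
    ncd_intercept: float = -0.35
    ncd_age_slope: float = 0.02
    cd_share_of_non_ncd: float = 0.35
    ip_rate_elderly: float = 0.20
    ip_rate_other: float = 0.05
    op_rate_elderly: float = 0.25
    op_rate_other: float = 0.08
    op_extra_visits_mean: float = 0.7
    op_offgroup_visit_prob: float = 0.15
    # facility choice: P(private) = sigmoid(intercept + g * class_index)
    choice_intercept: float = -0.35
    private_gradient: float = 0.4
    # cost model (locations are modes, INR)
    ip_base_location: dict[str, float] = Field(
        default_factory=lambda: {"rural": 18250.0, "urban": 26250.0}
    )
    op_base_location: dict[str, float] = Field(
        default_factory=lambda: {"rural": 525.0, "urban": 725.0}
    )
    ip_duration_multipliers: tuple[float, float, float, float] = (
        1.0, 1.5, 2.2, 3.5
    )
    op_duration_multipliers: tuple[float, float, float, float] = (
        1.0, 1.3, 1.7, 2.2
    )
    class_cost_multipliers: tuple[float, float, float, float] = (
        1.0, 1.0, 1.0, 1.0
    )
    state_cost_factors: list[float] | None = None
    ip_peak_offset: float = 300.0
    op_peak_offset: float = 30.0
    cost_sigma: float = 1.0
    public_fraction: float = 0.3
    public_noise_sd: float = 0.25
    component_alphas: dict[str, tuple[float, float, float, float]] = Field(
        default_factory=lambda: {
            "IP": (3.5, 4.5, 1.0, 1.0),
            "OP": (7.0, 1.5, 1.0, 0.5),
        }
    )
    # duration draws
    stay_log_mean: float = math.log(4.0)
    stay_log_sd: float = 0.9
    opdur_log_mean: float = math.log(30.0)
    opdur_log_sd: float = 1.2

    @model_validator(mode="after")
    def _check(self):
        rates = [
            self.elderly_fraction, self.cd_share_of_non_ncd,
            self.ip_rate_elderly, self.ip_rate_other,
            self.op_rate_elderly, self.op_rate_other,
            self.op_offgroup_visit_prob, self.public_fraction,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.households_per_state_sector < 1:
            raise ValueError("households_per_state_sector must be >= 1")
        for name in ("log_sd_expenditure", "cost_sigma", "public_noise_sd",
                     "ip_peak_offset", "op_peak_offset", "weight_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.state_expenditure_shift is not None and len(
            self.state_expenditure_shift
        ) != self.n_states:
            raise ValueError("state_expenditure_shift length != n_states")
        if self.state_cost_factors is not None and len(
            self.state_cost_factors
        ) != self.n_states:
            raise ValueError("state_cost_factors length != n_states")
        min_op_loc = min(self.op_base_location.values()) * min(
            self.op_duration_multipliers
        ) * min(self.class_cost_multipliers)
        if self.op_peak_offset > min_op_loc:
            raise ValueError("op_peak_offset exceeds smallest OP location")
        return self

    def expected_ip_ncd_elderly_per_household(self) -> float:
        """Rough expected yield of elderly NCD hospitalizations/household."""
        p_ncd = 1.0 / (1.0 + math.exp(-(self.ncd_intercept
                                        + self.ncd_age_slope * 8.0)))
        return (self.mean_household_size * self.elderly_fraction
                * self.ip_rate_elderly * p_ncd)

    def with_target_ip_episodes(self, n_episodes: int, **overrides):
        """Scale the household frame to an expected elderly-NCD IP count."""
        cfg = self.model_copy(update=overrides)
        per_hh = cfg.expected_ip_ncd_elderly_per_household()
        cells = cfg.n_states * 2
        hps = max(4, math.ceil(n_episodes / (per_hh * cells)))
        return cfg.model_copy(
            update={"households_per_state_sector": hps}
        )


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`generate`.

    ``ip``/``op`` hold one row per *analysis-set* public episode (elderly,
    all-NCD) with the true cost location and true net subsidy
    ``max(location - public OOPE, 0)``.  ``class_benefit_shares`` and
    ``class_utilization`` are per service and sector (rural / urban /
    combine), classes ordered poorest to richest; benefit shares use the
    same utilization-rate weighting as the pipeline
    (pi_j = delta_j * sum w * gamma).
    """

    gradient: float
    stratum_locations: pd.DataFrame
    ip: pd.DataFrame
    op: pd.DataFrame
    class_benefit_shares: dict = field(default_factory=dict)
    class_utilization: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "gradient": self.gradient,
                "class_benefit_shares": self.class_benefit_shares,
                "class_utilization": self.class_utilization,
                "true_ci_equal_population": {
                    svc: {
                        sec: true_concentration_index(self, svc, sec)
                        for sec in shares
                    }
                    for svc, shares in self.class_benefit_shares.items()
                },
            },
            indent=2,
        )


def true_concentration_index(
    truth: TruthRecord, service: str = "IP", sector: str = "combine",
    population: str = "equal",
) -> float:
    """Grouped-formula index of the planted class benefit shares.

    ``population="equal"`` uses class population shares of 0.25 each (the
    four classes are population quartiles by construction);
    ``population="utilization"`` uses the classes' planted shares of
    public episodes — the population actually ranked by the episode-level
    estimator, hence the matched recovery target when utilization is
    class-graded.
    """
    if not truth.class_benefit_shares:
        raise ValueError("TruthRecord has no planted benefit shares")
    shares = truth.class_benefit_shares[service][sector]
    if population == "equal":
        pops = [0.25, 0.25, 0.25, 0.25]
    elif population == "utilization":
        pops = truth.class_utilization[service][sector]
    else:
        raise ValueError(f"unknown population {population!r}")
    return grouped_concentration_index(shares, pops)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _ids(prefix: str, n: int) -> np.ndarray:
    """Opaque record ids, vectorized (zero-padded for stable sorting)."""
    return np.char.add(
        prefix, np.char.zfill(np.arange(n).astype("U8"), 8)
    ).astype(object)


def _band_index(service: str, days, bands) -> np.ndarray:
    labels = duration_band(service, days, bands)
    order = {}
    for i, (lo, hi) in enumerate(bands):
        order[f"{lo}-{hi}" if hi is not None else f"{lo}+"] = i
    return np.asarray([order[b] for b in labels], dtype=int)


def _locations(cfg: SimConfig, service: str, sector_codes, band_idx,
               class_idx, state_idx) -> np.ndarray:
    base = cfg.ip_base_location if service == "IP" else cfg.op_base_location
    mults = (cfg.ip_duration_multipliers if service == "IP"
             else cfg.op_duration_multipliers)
    state_fac = np.asarray(
        cfg.state_cost_factors
        if cfg.state_cost_factors is not None else [1.0] * cfg.n_states
    )
    base_arr = np.where(sector_codes == 0, base["rural"], base["urban"])
    return (base_arr
            * np.asarray(mults)[band_idx]
            * np.asarray(cfg.class_cost_multipliers)[class_idx]
            * state_fac[state_idx])


def draw_oope(
    locations, facility_private, service: str, cfg: SimConfig,
    rng: np.random.Generator,
):
    """Draw OOPE components for episodes with given true cost locations.

    Private totals: shifted lognormal with mode exactly at the location
    (shift = location - peak_offset; the lognormal part has mode
    ``peak_offset`` and shape ``cost_sigma``).  Public totals: mean
    ``public_fraction * location`` with lognormal multiplicative noise.
    The total is split into (medicine, other medical, transport, other
    non-medical) by a Dirichlet draw with service-specific concentration.

    Returns ``(components, totals)`` with components of shape (n, 4).
    """
    locations = np.asarray(locations, dtype=float)
    n = locations.size
    s = cfg.ip_peak_offset if service == "IP" else cfg.op_peak_offset
    sigma = cfg.cost_sigma
    # mode of LN(mu, sigma) is exp(mu - sigma^2); solve mu for mode = s
    mu = math.log(s) + sigma**2
    ln_part = rng.lognormal(mean=mu, sigma=sigma, size=n)
    private_total = (locations - s) + ln_part
    noise = rng.normal(0.0, cfg.public_noise_sd, size=n)
    public_total = (cfg.public_fraction * locations
                    * np.exp(noise - cfg.public_noise_sd**2 / 2.0))
    total = np.where(facility_private, private_total, public_total)
    total = np.round(np.maximum(total, 0.0), 2)
    alphas = np.asarray(cfg.component_alphas[service], dtype=float)
    gammas = rng.gamma(shape=alphas, size=(n, 4))
    props = gammas / gammas.sum(axis=1, keepdims=True)
    components = np.round(props * total[:, None], 2)
    return components, total


def _weighted_class_table(df: pd.DataFrame, value_col: str):
    """(benefit shares, utilization shares) per class over one frame."""
    w = df["weight"].to_numpy(dtype=float)
    g = df[value_col].to_numpy(dtype=float)
    util = []
    wgamma = []
    wtot = w.sum()
    for cls in CLASS_ORDER:
        m = (df["mpce_class"] == cls).to_numpy()
        util.append(float(w[m].sum() / wtot) if wtot > 0 else 0.0)
        wgamma.append(float((w[m] * g[m]).sum()))
    pi = [d * s for d, s in zip(util, wgamma)]
    tot = sum(pi)
    shares = [p / tot if tot > 0 else 0.0 for p in pi]
    return shares, util


def generate(config: SimConfig, seed: int | None = None):
    """Generate a :class:`SurveyDataset` and its :class:`TruthRecord`.

    Identical configuration (including seed) yields identical output.
    The generated dataset passes :func:`healthbia.io.validate` with zero
    errors.
    """
    cfg = config if seed is None else config.model_copy(
        update={"seed": seed}
    )
    rng = np.random.default_rng(cfg.seed)
    states = [f"S{i + 1:02d}" for i in range(cfg.n_states)]
    sectors = ("rural", "urban")
    hps = cfg.households_per_state_sector

    # --- households ------------------------------------------------------
    state_idx_h = np.repeat(np.arange(cfg.n_states), 2 * hps)
    sector_code_h = np.tile(np.repeat(np.arange(2), hps), cfg.n_states)
    n_h = state_idx_h.size
    shift = np.asarray(
        cfg.state_expenditure_shift
        if cfg.state_expenditure_shift is not None
        else np.zeros(cfg.n_states)
    )
    logmean = np.where(
        sector_code_h == 0,
        cfg.log_mean_expenditure["rural"],
        cfg.log_mean_expenditure["urban"],
    ) + shift[state_idx_h]
    size = 1 + rng.poisson(cfg.mean_household_size - 1.0, size=n_h)
    # total expenditure scales with sqrt(household size) so that the
    # equivalized MPCE (T / sqrt(N)) is independent of size: class
    # membership then carries no household-size composition effect
    expenditure = np.round(
        np.exp(rng.normal(logmean + 0.5 * np.log(size),
                          cfg.log_sd_expenditure)), 2
    )
    weight = np.round(
        cfg.weight_base * rng.uniform(cfg.weight_low, cfg.weight_high, n_h),
        4,
    )
    households = pd.DataFrame(
        {
            "household_id": _ids("H", n_h),
            "state": np.asarray(states)[state_idx_h],
            "sector": np.where(sector_code_h == 0, "rural", "urban"),
            "total_monthly_expenditure": expenditure,
            "household_size": size.astype(int),
            "weight": weight,
        }
    )

    # planted MPCE class: same weighted-quartile rule the pipeline applies
    cutpoints, _ = mpce_cutpoints(households)
    hh = households.merge(cutpoints, on=["state", "sector"], how="left")
    mpce_h = equivalized_mpce(
        hh["total_monthly_expenditure"], hh["household_size"]
    )
    class_h = assign_class(mpce_h, hh["q25"], hh["q50"], hh["q75"])
    class_idx_h = np.asarray([_CLASS_INDEX[c] for c in class_h], dtype=int)

    # --- individuals -----------------------------------------------------
    hh_of_person = np.repeat(np.arange(n_h), size)
    n_i = hh_of_person.size
    is_elderly = rng.random(n_i) < cfg.elderly_fraction
    age = np.where(
        is_elderly,
        60 + np.minimum(
            np.floor(rng.exponential(cfg.elderly_age_scale, n_i)), 39
        ),
        np.floor(rng.uniform(0, 60, n_i)),
    ).astype(int)
    sex = np.where(rng.random(n_i) < 0.5, "F", "M")
    individuals = pd.DataFrame(
        {
            "person_id": _ids("P", n_i),
            "household_id": households["household_id"].to_numpy()[
                hh_of_person
            ],
            "age": age,
            "sex": sex,
            "weight": weight[hh_of_person],
        }
    )

    person_state_idx = state_idx_h[hh_of_person]
    person_sector_code = sector_code_h[hh_of_person]
    person_class_idx = class_idx_h[hh_of_person]
    person_mpce = np.asarray(mpce_h)[hh_of_person]
    person_weight = weight[hh_of_person]

    amap = default_ailment_map()
    group_codes = {
        g: np.asarray(
            [c for c, gg in amap.codes().items() if gg == g]
        )
        for g in ("CD", "NCD", "OD")
    }

    def draw_groups(ages, m):
        p_ncd = _sigmoid(cfg.ncd_intercept
                         + cfg.ncd_age_slope * (ages - 60.0))
        u = rng.random(m)
        groups = np.where(
            u < p_ncd, "NCD",
            np.where(rng.random(m) < cfg.cd_share_of_non_ncd, "CD", "OD"),
        )
        return groups

    def draw_codes(groups):
        codes = np.empty(groups.size, dtype=object)
        for g, pool in group_codes.items():
            m = groups == g
            if m.any():
                codes[m] = pool[rng.integers(0, pool.size, m.sum())]
        return codes

    # --- inpatient episodes ---------------------------------------------
    ip_rate = np.where(is_elderly, cfg.ip_rate_elderly, cfg.ip_rate_other)
    has_ip = rng.random(n_i) < ip_rate
    ip_person = np.flatnonzero(has_ip)
    n_ip = ip_person.size
    ip_group = draw_groups(age[ip_person].astype(float), n_ip)
    ip_code = draw_codes(ip_group)
    p_private = _sigmoid(cfg.choice_intercept
                         + cfg.private_gradient
                         * person_class_idx[ip_person])
    ip_private = rng.random(n_ip) < p_private
    stay = np.clip(
        np.ceil(rng.lognormal(cfg.stay_log_mean, cfg.stay_log_sd, n_ip)),
        1, 60,
    ).astype(int)
    ip_band = _band_index("IP", stay, DEFAULT_IP_BANDS)
    ip_loc = _locations(
        cfg, "IP", person_sector_code[ip_person], ip_band,
        person_class_idx[ip_person], person_state_idx[ip_person],
    )
    ip_comp, ip_total = draw_oope(ip_loc, ip_private, "IP", cfg, rng)
    inpatient = pd.DataFrame(
        {
            "episode_id": _ids("E", n_ip),
            "person_id": individuals["person_id"].to_numpy()[ip_person],
            "ailment_code": ip_code,
            "facility": np.where(ip_private, "private", "public"),
            "stay_days": stay,
            "oope_medicine": ip_comp[:, 0],
            "oope_other_medical": ip_comp[:, 1],
            "oope_transport": ip_comp[:, 2],
            "oope_other_nonmedical": ip_comp[:, 3],
            "weight": person_weight[ip_person],
        }
    )

    # --- outpatient spells ----------------------------------------------
    op_rate = np.where(is_elderly, cfg.op_rate_elderly, cfg.op_rate_other)
    has_op = rng.random(n_i) < op_rate
    op_person = np.flatnonzero(has_op)
    n_op = op_person.size
    op_group = draw_groups(age[op_person].astype(float), n_op)
    n_visits = 1 + rng.poisson(cfg.op_extra_visits_mean, n_op)
    visit_spell = np.repeat(np.arange(n_op), n_visits)
    n_visits_total = visit_spell.size
    off = rng.random(n_visits_total) < cfg.op_offgroup_visit_prob
    visit_group = np.repeat(op_group, n_visits).copy()
    if off.any():
        all_groups = np.asarray(["CD", "NCD", "OD"])
        visit_group[off] = all_groups[rng.integers(0, 3, off.sum())]
    visit_code = draw_codes(visit_group)
    # serialize per-spell visit code lists (visit_spell is already sorted);
    # one big buffer + offset slicing is much faster than a groupby join
    starts = np.searchsorted(visit_spell, np.arange(n_op))
    ends = np.append(starts[1:], n_visits_total)
    if n_op:
        lens = np.char.str_len(visit_code.astype(str)) + 1
        offsets = np.concatenate([[0], np.cumsum(lens)])
        buffer = ";".join(visit_code.tolist()) + ";"
        visit_codes_str = [
            buffer[offsets[a]:offsets[b] - 1] for a, b in zip(starts, ends)
        ]
        all_ncd = np.logical_and.reduceat(visit_group == "NCD", starts)
    else:
        visit_codes_str = []
        all_ncd = np.zeros(0, dtype=bool)
    op_dur = np.clip(
        np.round(rng.lognormal(cfg.opdur_log_mean, cfg.opdur_log_sd, n_op)),
        0, 2000,
    ).astype(int)
    p_private_op = _sigmoid(cfg.choice_intercept
                            + cfg.private_gradient
                            * person_class_idx[op_person])
    op_private = rng.random(n_op) < p_private_op
    op_band = _band_index("OP", op_dur, DEFAULT_OP_BANDS)
    op_loc = _locations(
        cfg, "OP", person_sector_code[op_person], op_band,
        person_class_idx[op_person], person_state_idx[op_person],
    )
    op_comp, op_total = draw_oope(op_loc, op_private, "OP", cfg, rng)
    outpatient = pd.DataFrame(
        {
            "spell_id": _ids("V", n_op),
            "person_id": individuals["person_id"].to_numpy()[op_person],
            "visit_ailment_codes": visit_codes_str,
            "ailment_duration_days": op_dur,
            "facility": np.where(op_private, "private", "public"),
            "oope_medicine": op_comp[:, 0],
            "oope_other_medical": op_comp[:, 1],
            "oope_transport": op_comp[:, 2],
            "oope_other_nonmedical": op_comp[:, 3],
            "weight": person_weight[op_person],
        }
    )

    dataset = SurveyDataset(
        households=households,
        individuals=individuals,
        inpatient=inpatient,
        outpatient=outpatient,
    )

    # --- ground truth ----------------------------------------------------
    class_labels = np.asarray(CLASS_ORDER, dtype=object)

    def truth_frame(persons, ids, private, elig_ncd, loc, total, sector_code,
                    cls_idx):
        public = ~private
        m = public & elig_ncd
        subsidy = np.maximum(loc - total, 0.0)
        return pd.DataFrame(
            {
                "id": np.asarray(ids, dtype=object)[m],
                "sector": np.where(sector_code[m] == 0, "rural", "urban"),
                "mpce_class": class_labels[cls_idx[m]],
                "mpce": person_mpce[persons][m],
                "weight": person_weight[persons][m],
                "true_location": loc[m],
                "true_subsidy": subsidy[m],
            }
        )

    ip_elig = (age[ip_person] >= 60) & (ip_group == "NCD")
    ip_truth = truth_frame(
        ip_person, inpatient["episode_id"].to_numpy(), ip_private, ip_elig,
        ip_loc, ip_total, person_sector_code[ip_person],
        person_class_idx[ip_person],
    )
    op_elig = (age[op_person] >= 60) & all_ncd
    op_truth = truth_frame(
        op_person, outpatient["spell_id"].to_numpy(), op_private, op_elig,
        op_loc, op_total, person_sector_code[op_person],
        person_class_idx[op_person],
    )

    shares: dict = {}
    utilization: dict = {}
    for svc, frame in (("IP", ip_truth), ("OP", op_truth)):
        shares[svc] = {}
        utilization[svc] = {}
        for sector in ("rural", "urban", "combine"):
            sdf = frame if sector == "combine" else frame[
                frame["sector"] == sector
            ]
            if len(sdf) == 0:
                continue
            s, u = _weighted_class_table(sdf, "true_subsidy")
            shares[svc][sector] = s
            utilization[svc][sector] = u

    loc_rows = []
    for svc, bands, persons, band_idx, loc in (
        ("IP", DEFAULT_IP_BANDS, ip_person, ip_band, ip_loc),
        ("OP", DEFAULT_OP_BANDS, op_person, op_band, op_loc),
    ):
        frame = pd.DataFrame(
            {
                "service": svc,
                "state": np.asarray(states)[person_state_idx[persons]],
                "sector": np.where(
                    person_sector_code[persons] == 0, "rural", "urban"
                ),
                "mpce_class": class_labels[person_class_idx[persons]],
                "duration_band": [
                    f"{lo}-{hi}" if hi is not None else f"{lo}+"
                    for lo, hi in (bands[i] for i in band_idx)
                ],
                "true_location": loc,
            }
        ).drop_duplicates()
        loc_rows.append(frame)
    stratum_locations = pd.concat(loc_rows, ignore_index=True)

    truth = TruthRecord(
        gradient=cfg.private_gradient,
        stratum_locations=stratum_locations,
        ip=ip_truth,
        op=op_truth,
        class_benefit_shares=shares,
        class_utilization=utilization,
    )
    return dataset, truth


def write_dataset(dataset: SurveyDataset, out_dir) -> dict[str, Path]:
    """Write the four canonical CSVs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in dataset.tables().items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
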
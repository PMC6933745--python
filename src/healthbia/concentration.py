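"""Concentration curves and indices for the distribution of subsidy benefit.

The concentration curve plots the cumulative share of subsidy benefit
against the cumulative population share when records are ranked from
poorest to richest by equivalized MPCE.  The concentration index C is
twice the (signed) area between the curve and the 45-degree line of
equality: negative when the curve lies above the diagonal (pro-poor),
positive below it (pro-rich).  With midpoint fractional ranks r_i the
index has the weighted covariance form

    C = (2 / mu) * sum_i w~_i (h_i - mu)(r_i - r~),

which coincides exactly with the trapezoid area of the curve through the
same points.  Robust standard errors come from the "convenient
regression": weighted least squares of 2*var_w(r)*h_i/mu on r_i, whose
slope is algebraically identical to C, with an HC1 covariance and t-based
p-values (no clustering by default; household-cluster SEs are available).

The default ranking variable is the individual's *continuous* equivalized
MPCE with stable tie-breaking — a four-level class rank would make the
micro index ill-defined — but ranking by class is available as an option.
Curve confidence bands are pointwise 2.5/97.5 percentile bands from a
household-level bootstrap (households resampled with replacement, their
episodes following them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .schema import CLASS_ORDER


def _normalize(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty input")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w / w.sum()


def _rank_order(mpce) -> np.ndarray:
    """Ascending sort order by mpce with a stable secondary key.

    Ties in mpce are broken by original record position, so class-level
    ties spread uniformly within the tied block.
    """
    return np.argsort(np.asarray(mpce, dtype=float), kind="stable")


def fractional_rank(mpce, weights) -> np.ndarray:
    """Weighted midpoint fractional ranks in (0, 1), aligned with input.

    r_i = (cumulative normalized weight of strictly preceding records)
          + w~_i / 2, in ascending mpce order.
    """
    wt = _normalize(weights)
    order = _rank_order(mpce)
    w_sorted = wt[order]
    ranks_sorted = np.cumsum(w_sorted) - w_sorted / 2.0
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return ranks


def concentration_index(h, ranks, weights) -> float:
    """Weighted covariance form C = (2/mu) cov_w(h, r).

    Undefined (NaN, with a warning) when the weighted mean of h is zero.
    """
    h = np.asarray(h, dtype=float)
    r = np.asarray(ranks, dtype=float)
    wt = _normalize(weights)
    mu = float(np.sum(wt * h))
    if mu == 0:
        import sys

        print("concentration_index: mean benefit is zero; index undefined",
              file=sys.stderr)
        return float("nan")
    rbar = float(np.sum(wt * r))
    return float(2.0 / mu * np.sum(wt * (h - mu) * (r - rbar)))


def convenient_regression_se(
    h, ranks, weights, cluster=None
) -> tuple[float, float, float]:
    """(C, robust SE, p-value) from the convenient-regression estimator.

    Regresses y_i = 2*var_w(r)*h_i/mu on r_i by WLS; the slope equals the
    covariance-form index exactly.  SE is heteroskedasticity-robust (HC1),
    or CR (cluster-robust) when ``cluster`` labels are given; p-values use
    the t distribution with n-2 (or n_clusters-1) degrees of freedom.
    """
    h = np.asarray(h, dtype=float)
    r = np.asarray(ranks, dtype=float)
    w = np.asarray(weights, dtype=float)
    if h.size < 3:
        raise ValueError("need at least 3 observations")
    wt = w / w.sum()
    mu = float(np.sum(wt * h))
    if mu == 0:
        raise ValueError("mean benefit is zero")
    rbar = float(np.sum(wt * r))
    var_r = float(np.sum(wt * (r - rbar) ** 2))
    if var_r <= 0:
        raise ValueError("degenerate regressor: ranks have zero variance")
    y = 2.0 * var_r * h / mu
    X = sm.add_constant(r)
    model = sm.WLS(y, X, weights=w)
    if cluster is not None:
        fit = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": np.asarray(cluster)},
            use_t=True,
        )
    else:
        fit = model.fit(cov_type="HC1", use_t=True)
    slope, se, p = (float(fit.params[1]), float(fit.bse[1]),
                    float(fit.pvalues[1]))
    if se == 0.0:  # exact fit (e.g. constant h): no evidence against 0
        p = 1.0 if slope == 0.0 else 0.0
    return slope, se, p


def concentration_curve(h, mpce, weights) -> np.ndarray:
    """Curve points (cum. population share, cum. benefit share).

    Records are sorted poorest to richest (stable ties); the point list is
    prepended with (0, 0) and ends at (1, 1); the curve is piecewise
    linear between points.  Fatal when total benefit is zero.
    """
    h = np.asarray(h, dtype=float)
    wt = _normalize(weights)
    order = _rank_order(mpce)
    hw = wt[order] * h[order]
    total = hw.sum()
    if total == 0:
        raise ValueError("total benefit is zero: curve undefined")
    p = np.concatenate([[0.0], np.cumsum(wt[order])])
    L = np.concatenate([[0.0], np.cumsum(hw) / total])
    p[-1] = 1.0
    L[-1] = 1.0
    return np.column_stack([p, L])


def curve_area_index(curve: np.ndarray) -> float:
    """Twice the trapezoid area between the 45-degree line and the curve.

    Independent geometric route to the concentration index (positive when
    the curve lies below the diagonal).
    """
    p, L = curve[:, 0], curve[:, 1]
    diff = p - L
    return float(2.0 * np.trapezoid(diff, p))


def curve_on_grid(curve: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, curve[:, 0], curve[:, 1])


def grouped_concentration_index(benefit_shares, population_shares) -> float:
    """Index from grouped data, groups ordered poorest to richest.

    C = sum_{t=1}^{T-1} (p_t * L_{t+1} - p_{t+1} * L_t) on cumulative
    population shares p and cumulative benefit shares L.
    """
    s = np.asarray(benefit_shares, dtype=float)
    q = np.asarray(population_shares, dtype=float)
    if np.any(s < 0) or np.any(q < 0):
        raise ValueError("shares must be nonnegative")
    # tolerate printed-table rounding (e.g. shares summing to 100.01%)
    if abs(s.sum() - 1.0) > 5e-3 or abs(q.sum() - 1.0) > 5e-3:
        raise ValueError("shares must each sum to 1")
    s = s / s.sum()
    q = q / q.sum()
    p = np.cumsum(q)
    L = np.cumsum(s)
    return float(np.sum(p[:-1] * L[1:] - p[1:] * L[:-1]))


@dataclass
class ConcentrationResult:
    """Index, inference and curve for one (service, sector) cell."""

    index: float
    robust_se: float
    p_value: float
    n_obs: int
    curve: np.ndarray
    band_grid: np.ndarray | None = None
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    label: str = ""

    def to_json(self) -> str:
        payload = {
            "label": self.label,
            "index": self.index,
            "robust_se": self.robust_se,
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "curve": self.curve.tolist(),
        }
        if self.band_grid is not None:
            payload["band_grid"] = self.band_grid.tolist()
            payload["band_lower"] = self.band_lower.tolist()
            payload["band_upper"] = self.band_upper.tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ConcentrationResult":
        d = json.loads(text)
        return cls(
            index=d["index"], robust_se=d["robust_se"],
            p_value=d["p_value"], n_obs=d["n_obs"],
            curve=np.asarray(d["curve"], dtype=float),
            band_grid=(np.asarray(d["band_grid"])
                       if "band_grid" in d else None),
            band_lower=(np.asarray(d["band_lower"])
                        if "band_lower" in d else None),
            band_upper=(np.asarray(d["band_upper"])
                        if "band_upper" in d else None),
            label=d.get("label", ""),
        )


def bootstrap_band(
    df: pd.DataFrame,
    B: int = 500,
    seed: int = 0,
    n_grid: int = 100,
    h_col: str = "h",
    mpce_col: str = "mpce",
    weight_col: str = "weight",
    household_col: str = "household_id",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise 95% band for the concentration curve.

    Households are resampled with replacement B times; each household's
    episodes follow it (its weight is multiplied by the number of times it
    was drawn).  The curve is evaluated on a fixed grid of population
    shares and the band is the pointwise 2.5/97.5 percentile envelope.
    Deterministic given ``seed``.  Refuses datasets with fewer than 10
    households.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    households = df[household_col].unique()
    n_hh = households.size
    if n_hh < 10:
        raise ValueError(
            f"bootstrap_band: only {n_hh} households (< 10); refusing"
        )
    hh_index = pd.Series(np.arange(n_hh), index=households)
    row_hh = hh_index[df[household_col]].to_numpy()
    h = df[h_col].to_numpy(dtype=float)
    mpce = df[mpce_col].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float)

    grid = np.linspace(0.0, 1.0, n_grid)
    rng = np.random.default_rng(seed)
    curves = np.empty((B, n_grid))
    for b in range(B):
        counts = np.bincount(
            rng.integers(0, n_hh, size=n_hh), minlength=n_hh
        )
        mult = counts[row_hh]
        keep = mult > 0
        if not keep.any() or (h[keep] * w[keep] * mult[keep]).sum() == 0:
            curves[b] = grid  # degenerate resample: diagonal
            continue
        curve = concentration_curve(
            h[keep], mpce[keep], w[keep] * mult[keep]
        )
        curves[b] = curve_on_grid(curve, grid)
    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    return grid, lower, upper


def class_rank_values(mpce_class, mpce=None) -> np.ndarray:
    """Ranking variable from the 4-level class (option to the default).

    Maps P < LM < UM < R to 0..3; ties within a class are then broken by
    the stable secondary key in :func:`fractional_rank`.
    """
    lookup = {cls: i for i, cls in enumerate(CLASS_ORDER)}
    return np.asarray([lookup[c] for c in mpce_class], dtype=float)


def compute_concentration(
    df: pd.DataFrame,
    h_col: str = "h",
    mpce_col: str = "mpce",
    weight_col: str = "weight",
    rank_by: str = "continuous",
    cluster_col: str | None = None,
    bootstrap: int = 0,
    seed: int = 0,
    label: str = "",
) -> ConcentrationResult:
    """Index + robust inference + curve (+ optional bootstrap band)."""
    if rank_by == "continuous":
        rank_var = df[mpce_col].to_numpy(dtype=float)
    elif rank_by == "class":
        rank_var = class_rank_values(df["mpce_class"])
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    h = df[h_col].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float)
    ranks = fractional_rank(rank_var, w)
    C, se, p = convenient_regression_se(
        h, ranks, w,
        cluster=df[cluster_col] if cluster_col else None,
    )
    curve = concentration_curve(h, rank_var, w)
    result = ConcentrationResult(
        index=C, robust_se=se, p_value=p, n_obs=len(df), curve=curve,
        label=label,
    )
    if bootstrap:
        grid, lo, hi = bootstrap_band(
            df.assign(_rank=rank_var), B=bootstrap, seed=seed,
            h_col=h_col, mpce_col="_rank", weight_col=weight_col,
        )
        result.band_grid, result.band_lower, result.band_upper = grid, lo, hi
    return result


def plot_concentration_curves(results: dict, path) -> None:
    """45-degree line, curves and shaded 95% bands, one panel per service."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    services = sorted(results)
    fig, axes = plt.subplots(
        1, len(services), figsize=(5.2 * len(services), 4.6), squeeze=False
    )
    for ax, service in zip(axes[0], services):
        ax.plot([0, 1], [0, 1], color="black", lw=1, label="equality")
        for sector, res in results[service].items():
            (line,) = ax.plot(
                res.curve[:, 0], res.curve[:, 1], lw=1.5, label=sector
            )
            if res.band_grid is not None:
                ax.fill_between(
                    res.band_grid, res.band_lower, res.band_upper,
                    color=line.get_color(), alpha=0.18, lw=0,
                )
        ax.set_title(f"{service} care")
        ax.set_xlabel("cumulative population share (poorest first)")
        ax.set_ylabel("cumulative subsidy share")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
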
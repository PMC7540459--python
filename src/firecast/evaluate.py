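"""Diagnostics and forecast verification.

Diagnostics: per-region trend slope, KPSS stationarity tests (level and
trend null), and ACF/PACF of the deseasonalized series — the checks that
motivate the differencing range, AR/MA order ranges, and the anomaly
transform.

Verification: anomaly correlation and RMSE per (variant, lead), globally
(on the summed series) and per region, plus the percent RMSE change
against the climatology baseline (negative means the variant beats
climatology) and per-region best-model tables.  Observed anomalies always
use the development-period climatology, also during the prediction period,
so skill is measured against what was known when the system was built.
Unverifiable records (target month beyond the observed record) are ignored
and every reported score carries its sample count.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import kpss as _sm_kpss
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .forecast import VARIANT_ORDER
from .io import RegionSeries
from .transform import MonthlyClimatology

__all__ = [
    "acf",
    "pacf",
    "trend_and_kpss",
    "anomaly_corr",
    "rmse",
    "pct_rmse_vs_clim",
    "attach_observations",
    "restrict_common_targets",
    "skill_report",
    "global_series",
    "best_model_map",
]


def acf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation r[0..max_lag]; r[0] = 1."""
    series = np.asarray(series, dtype=float)
    if len(series) <= max_lag + 2:
        raise ValueError("series too short for requested lag")
    if series.std() == 0:
        raise ValueError("constant series: autocorrelation undefined")
    return _sm_acf(series, nlags=max_lag, fft=True)


def pacf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Partial autocorrelation phi[1..max_lag] via Durbin-Levinson."""
    series = np.asarray(series, dtype=float)
    if len(series) <= max_lag + 2:
        raise ValueError("series too short for requested lag")
    if series.std() == 0:
        raise ValueError("constant series: partial autocorrelation undefined")
    return _sm_pacf(series, nlags=max_lag, method="ld")[1:]


def trend_and_kpss(series: pd.Series) -> dict:
    """Trend slope of the annual totals and KPSS stationarity statistics.

    Returns slope (units/yr from OLS on calendar-year totals), the KPSS
    statistic for the level ('c') and trend ('ct') nulls with their 5%
    rejection flags; the Newey-West lag truncation is the classic
    floor(4*(T/100)^0.25).
    """
    annual = series.groupby(series.index.year).sum()
    if len(annual) < 5:
        raise ValueError("need at least 5 years for a trend")
    t = annual.index.values.astype(float)
    slope = float(np.polyfit(t - t.mean(), annual.values, 1)[0])
    x = series.values.astype(float)
    out = {"slope_per_year": slope}
    for reg, key in (("c", "level"), ("ct", "trend")):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, pval, *_ = _sm_kpss(x, regression=reg, nlags="legacy")
        out[f"kpss_{key}_stat"] = float(stat)
        out[f"kpss_{key}_reject_5pct"] = bool(pval < 0.05)
    return out


def attach_observations(records: pd.DataFrame, region_series: RegionSeries,
                        clims: dict[int, MonthlyClimatology]) -> pd.DataFrame:
    """Join observed emissions and dev-climatology means onto the records.

    Adds ``observed`` (Tg C/month), ``clim_mean`` of the target month, and
    the prediction/observation anomalies.  Unverifiable records are dropped.
    """
    recs = records[records["verifiable"]].copy()
    obs = region_series.emissions
    t_idx = pd.PeriodIndex.from_fields(year=recs["target_year"],
                                       month=recs["target_month"], freq="M")
    observed = np.empty(len(recs))
    clim_mean = np.empty(len(recs))
    fcr_arr = recs["fcr_id"].values
    month_arr = recs["target_month"].values
    pos = obs.index.get_indexer(t_idx)
    for k, (fid, p, m) in enumerate(zip(fcr_arr, pos, month_arr)):
        observed[k] = obs[fid].values[p] if p >= 0 else np.nan
        clim_mean[k] = clims[fid].mean[m - 1]
    recs["observed"] = observed
    recs["clim_mean"] = clim_mean
    recs = recs.dropna(subset=["observed"])
    recs["pred_anom"] = recs["emission_pred"] - recs["clim_mean"]
    recs["obs_anom"] = recs["observed"] - recs["clim_mean"]
    return recs


def anomaly_corr(pred_anom: np.ndarray, obs_anom: np.ndarray) -> float:
    """Pearson r between prediction and observation anomalies (NaN if a
    side has zero variance, e.g. the Clim variant)."""
    pred_anom = np.asarray(pred_anom, dtype=float)
    obs_anom = np.asarray(obs_anom, dtype=float)
    if len(pred_anom) < 3:
        raise ValueError("need at least 3 verifiable pairs")
    # variance threshold is relative to the anomaly scale so that pure
    # round-trip noise (e.g. a climatology forecast re-read from CSV) still
    # counts as a constant prediction
    scale = max(np.abs(pred_anom).max(), np.abs(obs_anom).max(), 1e-300)
    if pred_anom.std() <= 1e-9 * scale or obs_anom.std() <= 1e-9 * scale:
        return np.nan
    return float(np.corrcoef(pred_anom, obs_anom)[0, 1])


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) == 0:
        raise ValueError("no records to score")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pct_rmse_vs_clim(variant_rmse: float, clim_rmse: float) -> float:
    """Percent RMSE change vs the climatology baseline; negative = better."""
    if not clim_rmse > 0:
        raise ValueError("climatology RMSE must be positive")
    return 100.0 * (variant_rmse - clim_rmse) / clim_rmse


def restrict_common_targets(recs: pd.DataFrame) -> pd.DataFrame:
    """Keep only target months scored at every lead (common-sample scores).

    RMSE comparisons across leads are only meaningful on a shared set of
    target months: each lead verifies over a differently shifted window, so
    raw per-lead scores mix skill with month composition (visible as a
    lead-dependent RMSE even for the lead-independent climatology
    forecast).
    """
    n_leads = recs["lead"].nunique()
    key = ["variant", "fcr_id", "target_year", "target_month"]
    counts = recs.groupby(key)["lead"].transform("nunique")
    return recs[counts == n_leads]


def global_series(recs: pd.DataFrame) -> pd.DataFrame:
    """Global-sum predicted and observed series per (variant, lead, month).

    Months missing any region are excluded so the sum is always over the
    same set of regions.
    """
    n_fcr = recs["fcr_id"].nunique()
    grp = recs.groupby(["variant", "lead", "target_year", "target_month"])
    agg = grp.agg(pred=("emission_pred", "sum"), obs=("observed", "sum"),
                  clim=("clim_mean", "sum"), n=("fcr_id", "nunique")).reset_index()
    return agg[agg["n"] == n_fcr].drop(columns="n")


def skill_report(recs: pd.DataFrame, include_global: bool = True) -> pd.DataFrame:
    """Scores per (variant, lead) at FCR scope and global scope.

    FCR scope pools nothing: each (variant, lead, fcr) row scores that
    region's verifiable records.  Global scope scores the global-sum series
    (the anomaly uses the summed development climatology).  The percent
    RMSE change is relative to the Clim variant at the same lead and scope.
    """
    rows = []
    for (variant, lead, fid), g in recs.groupby(["variant", "lead", "fcr_id"]):
        rows.append({
            "variant": variant, "lead": lead, "scope": fid, "n": len(g),
            "r_anomaly": anomaly_corr(g["pred_anom"].values, g["obs_anom"].values)
            if len(g) >= 3 else np.nan,
            "rmse": rmse(g["emission_pred"].values, g["observed"].values),
        })
    if include_global:
        glob = global_series(recs)
        for (variant, lead), g in glob.groupby(["variant", "lead"]):
            pred_anom = g["pred"].values - g["clim"].values
            obs_anom = g["obs"].values - g["clim"].values
            rows.append({
                "variant": variant, "lead": lead, "scope": "global", "n": len(g),
                "r_anomaly": anomaly_corr(pred_anom, obs_anom)
                if len(g) >= 3 else np.nan,
                "rmse": rmse(g["pred"].values, g["obs"].values),
            })
    rep = pd.DataFrame(rows)
    clim = rep[rep["variant"] == "Clim"].set_index(["lead", "scope"])["rmse"]
    pct = []
    for _, row in rep.iterrows():
        base = clim.get((row["lead"], row["scope"]), np.nan)
        pct.append(pct_rmse_vs_clim(row["rmse"], base)
                   if np.isfinite(base) and base > 0 else np.nan)
    rep["pct_rmse_vs_clim"] = pct
    return rep


def best_model_map(report: pd.DataFrame, lead: int) -> pd.DataFrame:
    """Winning (minimal-RMSE) variant per FCR at one lead.

    Ties break to the canonical variant order of the experiment table.
    """
    sub = report[(report["lead"] == lead) & (report["scope"] != "global")].copy()
    rank = {name: k for k, name in enumerate(VARIANT_ORDER)}
    sub["_rank"] = sub["variant"].map(rank)
    sub = sub.sort_values(["scope", "rmse", "_rank"], kind="mergesort")
    best = sub.groupby("scope").first().reset_index()
    return best[["scope", "variant", "rmse"]].rename(columns={"scope": "fcr_id"})
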
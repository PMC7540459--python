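"""Lagged cross-correlation analysis and the optimal-predictor lookup.

For each region the transformed emission anomaly is correlated with every
usable ocean climate index (OCI) and with the region's standardized VPD at
lags of 0..11 months over the development window.  For a forecast lead of L
months only lags in [L, 11] are operationally usable (the predictor value
for the target month must already be observed at the forecast origin), so
the lookup stores, per (region, lead): the (OCI, lag) pair maximizing |r|
jointly over usable indices and lags, and the VPD lag maximizing |r|.  Ties
break to the smaller lag, then to the canonical OCI order.  The lookup is
frozen from the development period and never updated during walk-forward
forecasting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LOOKUP_COLUMNS, OCISet, RegionSeries
from .transform import MonthlyClimatology, monthly_climatology, standardize_vpd, transform

__all__ = [
    "LagCorrTable",
    "lagged_xcorr",
    "select_optimal",
    "build_lookup",
    "MAX_LAG",
]

MAX_LAG = 11


@dataclass
class LagCorrTable:
    """|predictors| x |lags 0..11| Pearson correlations with flags.

    ``r[name][lag]`` is the correlation of the target at month t with the
    predictor at month t - lag over the development window; undefined
    correlations (zero variance) are stored as 0 and flagged.
    """

    r: pd.DataFrame  # index: predictor name, columns: lag 0..MAX_LAG
    flagged: pd.DataFrame  # same shape, True where r was undefined


def lagged_xcorr(target: pd.Series, predictor: pd.Series,
                 dev_window: tuple[int, int],
                 lags: range = range(0, MAX_LAG + 1)) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of (target_t, predictor_{t-lag}) for each lag.

    Returns (r, flagged); zero-variance pairings give r=0 with flag set.
    """
    y0, y1 = dev_window
    sel = (target.index.year >= y0) & (target.index.year <= y1)
    tgt = target[sel]
    r = np.zeros(len(lags))
    flagged = np.zeros(len(lags), dtype=bool)
    for k, lag in enumerate(lags):
        shifted = predictor.shift(lag).reindex(tgt.index)
        pair = pd.DataFrame({"y": tgt, "x": shifted}).dropna()
        if len(pair) < 24:
            raise ValueError("fewer than 24 overlapping months after shifting")
        y = pair["y"].values
        x = pair["x"].values
        if y.std() == 0 or x.std() == 0:
            flagged[k] = True
            continue
        r[k] = float(np.corrcoef(y, x)[0, 1])
    return r, flagged


def build_corr_table(target: pd.Series, ocis: OCISet, vpd_std: pd.Series | None,
                     dev_window: tuple[int, int]) -> LagCorrTable:
    """Correlation table over all usable OCIs (and VPD if provided)."""
    rows = {}
    flags = {}
    for name in ocis.usable_names:
        rows[name], flags[name] = lagged_xcorr(target, ocis.series(name), dev_window)
    if vpd_std is not None:
        rows["__VPD__"], flags["__VPD__"] = lagged_xcorr(target, vpd_std, dev_window)
    cols = list(range(MAX_LAG + 1))
    return LagCorrTable(pd.DataFrame(rows, index=cols).T,
                        pd.DataFrame(flags, index=cols).T.astype(bool))


def select_optimal(table: LagCorrTable, lead: int,
                   oci_order: list[str]) -> dict:
    """Pick the strongest usable (OCI, lag) pair and VPD lag for one lead.

    The signed correlation is stored.  If every candidate is flagged the
    entry carries a null predictor (the model then falls back to AR-only
    for that component).
    """
    if not (1 <= lead <= 6):
        raise ValueError("lead must be in 1..6")
    lags = range(lead, MAX_LAG + 1)
    entry = {"lead": lead, "oci_name": None, "oci_lag": np.nan, "oci_r": np.nan,
             "vpd_lag": np.nan, "vpd_r": np.nan}
    best = -1.0
    for lag in lags:  # lag-major order implements the tie-break
        for name in oci_order:
            if name not in table.r.index or table.flagged.loc[name, lag]:
                continue
            r = table.r.loc[name, lag]
            if abs(r) > best:
                best = abs(r)
                entry.update(oci_name=name, oci_lag=lag, oci_r=float(r))
    if "__VPD__" in table.r.index:
        best = -1.0
        for lag in lags:
            if table.flagged.loc["__VPD__", lag]:
                continue
            r = table.r.loc["__VPD__", lag]
            if abs(r) > best:
                best = abs(r)
                entry.update(vpd_lag=lag, vpd_r=float(r))
    return entry


def build_lookup(region_series: RegionSeries, ocis: OCISet,
                 dev_window: tuple[int, int],
                 leads: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
                 clims: dict[int, MonthlyClimatology] | None = None,
                 vpd_clims: dict[int, MonthlyClimatology] | None = None,
                 ) -> pd.DataFrame:
    """Per-(FCR, lead) optimal predictors from the development window.

    Correlations are computed on the transformed emission anomalies and on
    standardized VPD so predictor selection sees the same target the model
    is fit to.  Climatologies may be passed in (else derived here from the
    development window).
    """
    rows = []
    for fid in region_series.fcr_ids:
        emis = region_series.emissions[fid]
        clim = clims[fid] if clims else monthly_climatology(emis, dev_window)
        target = transform(emis, clim)
        vpd_std = None
        if region_series.vpd is not None:
            vser = region_series.vpd[fid]
            vclim = vpd_clims[fid] if vpd_clims else monthly_climatology(vser, dev_window)
            vpd_std = standardize_vpd(vser, vclim)
        table = build_corr_table(target, ocis, vpd_std, dev_window)
        for lead in leads:
            entry = select_optimal(table, lead, ocis.usable_names)
            entry["fcr_id"] = fid
            rows.append(entry)
    return pd.DataFrame(rows)[LOOKUP_COLUMNS]
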
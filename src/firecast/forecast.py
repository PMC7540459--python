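"""Walk-forward forecasting protocol and the seven model variants.

Variants (canonical order): OCIVPDAR (the reference ARIMAX with both the
optimal lagged OCI and lagged VPD as exogenous predictors), OCIAR, VPDAR
(one exogenous predictor each), ARonly (pure ARIMA), Xonly (static
regression, p=d=q=0), Clim (zero-anomaly monthly climatology) and
Persistence (the origin month's anomaly carried to every lead).

Hyperparameters — the optimal (OCI, lag), VPD lag and (p, d, q) per region
and lead — are frozen from the development window.  During the prediction
period every month is a forecast origin: the regression coefficients are
re-optimized on all data up to the origin, the fitted model is iterated
ahead, and the predicted anomaly (clipped to [-2, 2]) is mapped back to
emissions through the inverse transform.  Exogenous values for target
months are observed values at (target - lag), available because every lag
is at least the lead.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arimax import ORDER_GRID, ArimaxFit, ArimaxOrder, fit_arimax, fitted_values, forecast_mean, select_order
from .io import FORECAST_COLUMNS, OCISet, RegionSeries
from .predictors import build_lookup
from .transform import (
    MonthlyClimatology,
    monthly_climatology,
    standardize_vpd,
    transform,
)

__all__ = [
    "VariantSpec",
    "VARIANTS",
    "VARIANT_ORDER",
    "ForecastInputs",
    "prepare_inputs",
    "build_order_lookup",
    "forecast_origin",
    "run_variant",
    "hindcast_insample",
]

logger = logging.getLogger(__name__)

ANOMALY_BOUND = 2.0
DEFAULT_LEADS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class VariantSpec:
    """One row of the model-experiment table."""

    name: str
    use_oci: bool
    use_vpd: bool
    arima: str  # 'optimal' | 'zero' | 'none'


VARIANT_ORDER = ["OCIVPDAR", "OCIAR", "VPDAR", "ARonly", "Xonly", "Clim", "Persistence"]

VARIANTS: dict[str, VariantSpec] = {
    "OCIVPDAR": VariantSpec("OCIVPDAR", True, True, "optimal"),
    "OCIAR": VariantSpec("OCIAR", True, False, "optimal"),
    "VPDAR": VariantSpec("VPDAR", False, True, "optimal"),
    "ARonly": VariantSpec("ARonly", False, False, "optimal"),
    "Xonly": VariantSpec("Xonly", True, True, "zero"),
    "Clim": VariantSpec("Clim", False, False, "none"),
    "Persistence": VariantSpec("Persistence", False, False, "none"),
}


@dataclass
class ForecastInputs:
    """Everything the walk-forward sweep needs, frozen from development data."""

    region_series: RegionSeries
    ocis: OCISet
    dev_window: tuple[int, int]
    clims: dict[int, MonthlyClimatology]
    vpd_clims: dict[int, MonthlyClimatology] | None
    anomalies: pd.DataFrame  # transformed emission anomalies per FCR
    vpd_std: pd.DataFrame | None
    lag_lookup: pd.DataFrame

    @property
    def fcr_ids(self) -> list[int]:
        return list(self.anomalies.columns)

    @property
    def time(self) -> pd.PeriodIndex:
        return self.anomalies.index

    def lookup_entry(self, fid: int, lead: int) -> pd.Series:
        rows = self.lag_lookup[(self.lag_lookup.fcr_id == fid)
                               & (self.lag_lookup.lead == lead)]
        if len(rows) != 1:
            raise KeyError(f"no unique lookup entry for FCR {fid}, lead {lead}")
        return rows.iloc[0]


def prepare_inputs(region_series: RegionSeries, ocis: OCISet,
                   dev_window: tuple[int, int],
                   leads: tuple[int, ...] = DEFAULT_LEADS,
                   ddof: int = 1) -> ForecastInputs:
    """Build climatologies, transformed series and the predictor lookup.

    ``ddof`` is the climatology standard-deviation denominator correction
    (1 = sample convention).
    """
    clims = {fid: monthly_climatology(region_series.emissions[fid], dev_window,
                                      ddof=ddof)
             for fid in region_series.fcr_ids}
    anomalies = pd.DataFrame(
        {fid: transform(region_series.emissions[fid], clims[fid])
         for fid in region_series.fcr_ids}, index=region_series.time)
    vpd_clims = None
    vpd_std = None
    if region_series.vpd is not None:
        vpd_clims = {fid: monthly_climatology(region_series.vpd[fid], dev_window,
                                              ddof=ddof)
                     for fid in region_series.fcr_ids}
        vpd_std = pd.DataFrame(
            {fid: standardize_vpd(region_series.vpd[fid], vpd_clims[fid])
             for fid in region_series.fcr_ids}, index=region_series.time)
    lookup = build_lookup(region_series, ocis, dev_window, leads,
                          clims=clims, vpd_clims=vpd_clims)
    return ForecastInputs(region_series, ocis, dev_window, clims, vpd_clims,
                          anomalies, vpd_std, lookup)


def _exog_matrix(inputs: ForecastInputs, fid: int, lead: int,
                 variant: VariantSpec) -> pd.DataFrame | None:
    """Lag-shifted exogenous columns aligned to the anomaly time axis."""
    entry = inputs.lookup_entry(fid, lead)
    cols = {}
    if variant.use_oci and entry.oci_name is not None and pd.notna(entry.oci_name):
        shifted = inputs.ocis.series(entry.oci_name).shift(int(entry.oci_lag))
        cols["oci"] = shifted.reindex(inputs.time)
    if variant.use_vpd and inputs.vpd_std is not None and pd.notna(entry.vpd_lag):
        cols["vpd"] = inputs.vpd_std[fid].shift(int(entry.vpd_lag))
    if not cols:
        return None
    return pd.DataFrame(cols, index=inputs.time)


def _usable_start(exog: pd.DataFrame | None) -> int:
    """First row from which all exogenous columns are observed."""
    if exog is None:
        return 0
    finite = np.isfinite(exog.values).all(axis=1)
    idx = np.argmax(finite)
    if not finite.any():
        raise ValueError("exogenous columns never fully observed")
    return int(idx)


def _variant_order(variant: VariantSpec, order_lookup: pd.DataFrame | None,
                   fid: int, lead: int) -> ArimaxOrder:
    if variant.arima == "zero":
        return ArimaxOrder(0, 0, 0)
    if order_lookup is None:
        return ArimaxOrder(1, 0, 0)
    rows = order_lookup[(order_lookup.fcr_id == fid) & (order_lookup.lead == lead)]
    if len(rows) != 1:
        raise KeyError(f"no unique order entry for FCR {fid}, lead {lead}")
    r = rows.iloc[0]
    return ArimaxOrder(int(r.p), int(r.d), int(r.q))


def build_order_lookup(inputs: ForecastInputs, variant: VariantSpec | str = "OCIVPDAR",
                       leads: tuple[int, ...] = DEFAULT_LEADS,
                       grid: tuple[ArimaxOrder, ...] = ORDER_GRID,
                       diff_exog: bool = True) -> pd.DataFrame:
    """AIC-minimal (p, d, q) per (FCR, lead) on the development window.

    The exogenous columns are the variant's lead-specific lookup
    predictors; with no exogenous columns (ARonly) the selection is
    lead-independent and computed once.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    y0, y1 = inputs.dev_window
    dev_mask = (inputs.time.year >= y0) & (inputs.time.year <= y1)
    rows = []
    for fid in inputs.fcr_ids:
        shared: ArimaxOrder | None = None
        for lead in leads:
            exog = _exog_matrix(inputs, fid, lead, variant)
            if exog is None and shared is not None:
                order = shared
            else:
                s = _usable_start(exog)
                sel = dev_mask.copy()
                sel[:s] = False
                y = inputs.anomalies[fid].values[sel]
                x = exog.values[sel] if exog is not None else None
                order = select_order(y, x, grid, diff_exog)
                if exog is None:
                    shared = order
            rows.append({"fcr_id": fid, "lead": lead,
                         "p": order.p, "d": order.d, "q": order.q})
    return pd.DataFrame(rows)


def _invert_scalar(anomaly: float, clim: MonthlyClimatology, month: int) -> float:
    """Scalar inverse of the anomaly transform (hot path of record building)."""
    from .transform import ATANH_CLAMP

    mu = clim.mean[month - 1]
    sd = clim.sd[month - 1]
    u = min(max(anomaly / 2.0, -ATANH_CLAMP), ATANH_CLAMP)
    return max(mu + 2.0 * sd * float(np.arctanh(u)), 0.0)


def _record(fid, origin, lead, variant_name, anomaly, clim, time_axis):
    target = origin + lead
    emission = _invert_scalar(anomaly, clim, target.month)
    return {
        "fcr_id": fid,
        "origin_year": origin.year, "origin_month": origin.month,
        "lead": lead, "variant": variant_name,
        "anomaly_pred": anomaly, "emission_pred": emission,
        "target_year": target.year, "target_month": target.month,
        "verifiable": target <= time_axis[-1],
    }


def forecast_origin(inputs: ForecastInputs, origin: pd.Period,
                    variant: VariantSpec | str,
                    leads: tuple[int, ...] = DEFAULT_LEADS,
                    order_lookup: pd.DataFrame | None = None,
                    warm: dict | None = None) -> list[dict]:
    """All-lead forecasts issued at one origin month for every region."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    time_axis = inputs.time
    t0 = time_axis.get_loc(origin)
    records = []
    for fid in inputs.fcr_ids:
        clim = inputs.clims[fid]
        if variant.name == "Clim":
            for lead in leads:
                records.append(_record(fid, origin, lead, "Clim", 0.0, clim, time_axis))
            continue
        if variant.name == "Persistence":
            anom = float(inputs.anomalies[fid].iloc[t0])
            for lead in leads:
                records.append(_record(fid, origin, lead, "Persistence",
                                       anom, clim, time_axis))
            continue
        for lead in leads:
            try:
                rec = _forecast_one(inputs, fid, origin, t0, lead, variant,
                                    order_lookup, warm)
            except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
                logger.warning("forecast failed (fcr=%s origin=%s lead=%s): %s",
                               fid, origin, lead, exc)
                continue
            records.append(rec)
    return records


def _forecast_one(inputs, fid, origin, t0, lead, variant, order_lookup, warm):
    exog = _exog_matrix(inputs, fid, lead, variant)
    s = _usable_start(exog)
    if t0 - s + 1 < 24:
        raise ValueError("insufficient history at origin")
    y = inputs.anomalies[fid].values[s:t0 + 1]
    x = exog.values[s:t0 + 1] if exog is not None else None
    x_future = exog.values[t0 + 1:t0 + 1 + lead] if exog is not None else None
    if x_future is not None and (len(x_future) < lead
                                 or not np.isfinite(x_future).all()):
        raise ValueError("future exogenous values not observed")
    order = _variant_order(variant, order_lookup, fid, lead)
    key = (variant.name, fid, lead)
    start = warm.get(key) if warm is not None else None
    try:
        fit = fit_arimax(y, x, order, start_params=start)
        if not fit.converged:
            raise ValueError("non-convergence")
    except (ValueError, np.linalg.LinAlgError):
        # convergence fallback for this origin only
        fit = fit_arimax(y, x, ArimaxOrder(0, 0, 0))
        logger.warning("order %s fell back to (0,0,0) (fcr=%s origin=%s lead=%s)",
                       order.as_tuple(), fid, origin, lead)
    if warm is not None and fit.raw is not None and fit.order == order:
        warm[key] = fit.raw
    pred = forecast_mean(fit, y, x, x_future, lead)[lead - 1]
    anomaly = float(np.clip(pred, -ANOMALY_BOUND, ANOMALY_BOUND))
    return _record(fid, origin, lead, variant.name, anomaly,
                   inputs.clims[fid], inputs.time)


def run_variant(inputs: ForecastInputs, variant: VariantSpec | str,
                prediction_window: tuple[int, int],
                leads: tuple[int, ...] = DEFAULT_LEADS,
                order_lookup: pd.DataFrame | None = None,
                diff_exog: bool = True) -> pd.DataFrame:
    """Walk-forward sweep: every month of the prediction window is an origin.

    Origins whose target months fall beyond the observed record still
    produce records, flagged unverifiable so scores ignore them.
    ``diff_exog=False`` selects the literal recursion form in which
    exogenous columns stay undifferenced when d = 1.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if variant.arima == "optimal" and order_lookup is None:
        order_lookup = build_order_lookup(inputs, variant, leads,
                                          diff_exog=diff_exog)
    y0, y1 = prediction_window
    time_axis = inputs.time
    origin_pos = [k for k, t in enumerate(time_axis) if y0 <= t.year <= y1]
    if not origin_pos:
        raise ValueError("prediction window contains no observed months")
    records = []
    for fid in inputs.fcr_ids:
        clim = inputs.clims[fid]
        if variant.name in ("Clim", "Persistence"):
            anoms = inputs.anomalies[fid].values
            for t0 in origin_pos:
                origin = time_axis[t0]
                anom = 0.0 if variant.name == "Clim" else float(anoms[t0])
                for lead in leads:
                    records.append(_record(fid, origin, lead, variant.name,
                                           anom, clim, time_axis))
            continue
        for lead in leads:
            exog = _exog_matrix(inputs, fid, lead, variant)
            exog_vals = exog.values if exog is not None else None
            s = _usable_start(exog)
            order = _variant_order(variant, order_lookup, fid, lead)
            y_all = inputs.anomalies[fid].values
            warm_raw = None
            for t0 in origin_pos:
                origin = time_axis[t0]
                if t0 - s + 1 < 24:
                    logger.warning("insufficient history (fcr=%s origin=%s)",
                                   fid, origin)
                    continue
                y = y_all[s:t0 + 1]
                x = exog_vals[s:t0 + 1] if exog_vals is not None else None
                x_future = (exog_vals[t0 + 1:t0 + 1 + max(leads)]
                            if exog_vals is not None else None)
                if x_future is not None and (len(x_future) < lead
                                             or not np.isfinite(x_future[:lead]).all()):
                    logger.warning("future exog unobserved (fcr=%s origin=%s "
                                   "lead=%s)", fid, origin, lead)
                    continue
                try:
                    fit = fit_arimax(y, x, order, start_params=warm_raw,
                                     diff_exog=diff_exog)
                    if not fit.converged:
                        raise ValueError("non-convergence")
                except (ValueError, np.linalg.LinAlgError):
                    fit = fit_arimax(y, x, ArimaxOrder(0, 0, 0))
                    logger.warning("order %s fell back to (0,0,0) (fcr=%s "
                                   "origin=%s lead=%s)", order.as_tuple(), fid,
                                   origin, lead)
                if fit.order == order and fit.raw is not None:
                    warm_raw = fit.raw
                pred = forecast_mean(fit, y, x,
                                     None if x_future is None else x_future[:lead],
                                     lead)[lead - 1]
                anomaly = float(np.clip(pred, -ANOMALY_BOUND, ANOMALY_BOUND))
                records.append(_record(fid, origin, lead, variant.name, anomaly,
                                       clim, time_axis))
    return pd.DataFrame(records, columns=FORECAST_COLUMNS)


def hindcast_insample(inputs: ForecastInputs, variant: VariantSpec | str = "OCIVPDAR",
                      lead: int = 1,
                      order_lookup: pd.DataFrame | None = None) -> pd.DataFrame:
    """One-step-ahead fitted predictions over the development period.

    The model is fit once per region on the full development window; the
    Kalman one-step predictions play the role of in-sample lead-1 forecasts.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if variant.arima == "optimal" and order_lookup is None:
        order_lookup = build_order_lookup(inputs, variant, (lead,))
    y0, y1 = inputs.dev_window
    records = []
    for fid in inputs.fcr_ids:
        exog = _exog_matrix(inputs, fid, lead, variant)
        s = _usable_start(exog)
        dev_mask = (inputs.time.year >= y0) & (inputs.time.year <= y1)
        dev_mask[:s] = False
        idx = inputs.time[dev_mask]
        y = inputs.anomalies[fid].values[dev_mask]
        x = exog.values[dev_mask] if exog is not None else None
        if variant.name == "Clim":
            preds = np.zeros(len(y))
            d = 0
        elif variant.name == "Persistence":
            preds = np.concatenate([[y[0]], y[:-1]])
            d = 0
        else:
            order = _variant_order(variant, order_lookup, fid, lead)
            fit = fit_arimax(y, x, order)
            preds = fitted_values(fit, y, x)
            d = order.d
        clim = inputs.clims[fid]
        for k, t in enumerate(idx[d:]):
            anomaly = float(np.clip(preds[k], -ANOMALY_BOUND, ANOMALY_BOUND))
            records.append(_record(fid, t - lead, lead, variant.name, anomaly,
                                   clim, inputs.time))
    return pd.DataFrame(records, columns=FORECAST_COLUMNS)
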
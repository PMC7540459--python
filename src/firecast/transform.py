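"""Monthly climatology, the bounded anomaly transform, and VPD computation.

Fire emissions are strongly seasonal and right-skewed, so before fitting the
time-series model each regional series is reduced to a bounded anomaly:
remove the calendar-month climatological mean, divide by the interannual
standard deviation of that month, and pass through a scaled hyperbolic
tangent,

    y_hat_t = 2 * tanh((y_t - mean_m(t)) / (2 * sd_m(t))),

which restricts anomalies to [-2, 2] and damps extreme fire months.  The
climatology is always computed from the development window only, so the
transform never leaks information from the verification period.  VPD is
close to normal and is only standardized (no tanh).

Vapor pressure deficit comes from 2 m temperature, specific humidity and
surface pressure: saturation vapor pressure by the Clausius-Clapeyron
(Bolton) formula, actual vapor pressure from the water-vapor mixing ratio.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import VPDField

__all__ = [
    "MonthlyClimatology",
    "monthly_climatology",
    "transform",
    "inverse_transform",
    "standardize_vpd",
    "saturation_vp",
    "actual_vp",
    "vpd_field",
    "write_climatologies",
    "read_climatologies",
]

ATANH_CLAMP = 1.0 - 1e-6  # bound for y_hat/2 before atanh in the inverse
MW_RATIO = 0.622  # molecular weight ratio of water vapor to dry air


@dataclass
class MonthlyClimatology:
    """Per-calendar-month mean and interannual sd over the development window.

    ``mean``/``sd`` are length-12 arrays indexed by month-1; sd uses the
    sample (n-1) denominator.
    """

    mean: np.ndarray
    sd: np.ndarray
    dev_window: tuple[int, int]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (12,) or self.sd.shape != (12,):
            raise ValueError("climatology needs 12 monthly values")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")


def monthly_climatology(series: pd.Series, dev_window: tuple[int, int],
                        ddof: int = 1) -> MonthlyClimatology:
    """Across-year mean and sd of each calendar month within the window."""
    idx = series.index
    y0, y1 = dev_window
    sel = (idx.year >= y0) & (idx.year <= y1)
    sub = series[sel]
    mean = np.empty(12)
    sd = np.empty(12)
    for m in range(1, 13):
        vals = sub[sub.index.month == m].values
        if len(vals) < 2:
            raise ValueError(f"month {m} has fewer than 2 samples in {dev_window}")
        mean[m - 1] = vals.mean()
        sd[m - 1] = vals.std(ddof=ddof)
    return MonthlyClimatology(mean, sd, dev_window)


def _clim_arrays(index: pd.PeriodIndex, clim: MonthlyClimatology):
    m = index.month.values - 1
    return clim.mean[m], clim.sd[m]


def transform(series: pd.Series, clim: MonthlyClimatology) -> pd.Series:
    """Standardize-and-tanh anomaly transform; months with sd=0 map to 0."""
    mu, sd = _clim_arrays(series.index, clim)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (series.values - mu) / (2.0 * sd), 0.0)
    return pd.Series(2.0 * np.tanh(z), index=series.index)


def inverse_transform(anomalies: pd.Series, clim: MonthlyClimatology) -> pd.Series:
    """Back-transform anomalies to emissions; clamps atanh, floors at 0."""
    mu, sd = _clim_arrays(anomalies.index, clim)
    u = np.clip(np.asarray(anomalies.values, dtype=float) / 2.0,
                -ATANH_CLAMP, ATANH_CLAMP)
    y = mu + 2.0 * sd * np.arctanh(u)
    return pd.Series(np.maximum(y, 0.0), index=anomalies.index)


def standardize_vpd(series: pd.Series, clim: MonthlyClimatology) -> pd.Series:
    """Plain per-month standardization (no tanh); sd=0 months map to 0."""
    mu, sd = _clim_arrays(series.index, clim)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (series.values - mu) / sd, 0.0)
    return pd.Series(z, index=series.index)


def saturation_vp(t_celsius):
    """Saturation vapor pressure e_s (hPa) at air temperature T (deg C).

    Bolton's Clausius-Clapeyron fit: e_s = 6.112 * exp(17.67*T / (T + 243.5)).
    """
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= -243.5):
        raise ValueError("temperature must exceed -243.5 deg C")
    out = 6.112 * np.exp(17.67 * t / (t + 243.5))
    return float(out) if np.isscalar(t_celsius) else out


def actual_vp(qv, ps):
    """Actual vapor pressure e_a (hPa) from specific humidity (g/g) and
    surface pressure (hPa): e_a = Qv * Ps / 0.622."""
    qv = np.asarray(qv, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if np.any(qv < 0):
        raise ValueError("specific humidity must be non-negative")
    if np.any(ps <= 0):
        raise ValueError("surface pressure must be positive")
    out = qv * ps / MW_RATIO
    return float(out) if (out.ndim == 0) else out


def _coarsen(values: np.ndarray, factor: int, lat_centers: np.ndarray) -> np.ndarray:
    """Area-weighted (cos latitude) block mean onto a coarser grid."""
    nt, nlat, nlon = values.shape
    if nlat % factor or nlon % factor:
        raise ValueError("grid not divisible by coarsening factor")
    w = np.cos(np.deg2rad(lat_centers))[None, :, None]
    wv = values * w
    wv = wv.reshape(nt, nlat // factor, factor, nlon // factor, factor)
    ww = np.broadcast_to(w, values.shape).reshape(
        nt, nlat // factor, factor, nlon // factor, factor)
    return wv.sum(axis=(2, 4)) / ww.sum(axis=(2, 4))


def vpd_field(t_celsius: np.ndarray, qv: np.ndarray, ps: np.ndarray,
              time: pd.PeriodIndex, source_lat0: float = -90.0,
              lon0: float = -180.0, coarsen_factor: int = 1) -> VPDField:
    """VPD = e_s(T) - e_a(Qv, Ps) per source cell, optionally block-averaged
    onto a coarser (1-degree) target grid; floored at 0 hPa."""
    t_celsius = np.asarray(t_celsius, dtype=float)
    if t_celsius.shape != np.shape(qv) or t_celsius.shape != np.shape(ps):
        raise ValueError("T, Qv, Ps shapes must match")
    vpd = saturation_vp(t_celsius) - actual_vp(qv, ps)
    if coarsen_factor > 1:
        res = 1.0 / coarsen_factor  # source cell height in degrees
        src_lat = source_lat0 + res / 2 + res * np.arange(t_celsius.shape[1])
        vpd = _coarsen(vpd, coarsen_factor, src_lat)
    return VPDField(np.maximum(vpd, 0.0), time, lat0=source_lat0, lon0=lon0)


def write_climatologies(clims: dict[int, MonthlyClimatology], path: str | Path) -> Path:
    """Serialize per-FCR climatologies to CSV (fcr_id, month, mean, sd)."""
    rows = []
    for fid in sorted(clims):
        c = clims[fid]
        for m in range(12):
            rows.append({"fcr_id": fid, "month": m + 1,
                         "mean": c.mean[m], "sd": c.sd[m],
                         "dev_start": c.dev_window[0], "dev_end": c.dev_window[1]})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


def read_climatologies(path: str | Path) -> dict[int, MonthlyClimatology]:
    df = pd.read_csv(path)
    out = {}
    for fid, grp in df.groupby("fcr_id"):
        grp = grp.sort_values("month")
        out[int(fid)] = MonthlyClimatology(
            grp["mean"].values, grp["sd"].values,
            (int(grp["dev_start"].iloc[0]), int(grp["dev_end"].iloc[0])))
    return out
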
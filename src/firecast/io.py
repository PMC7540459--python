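"""Containers and readers/writers for the standard artifacts.

Gridded monthly fields travel as NetCDF (via :mod:`xarray`, scipy backend),
ocean-climate-index (OCI) series and forecast records as CSV, and the
per-region predictor lookup as CSV or JSON.  The grid convention is fixed:
1-degree cells, 0-based indices, cell (i, j) spanning
``[lat0 + i, lat0 + i + 1) x [lon0 + j, lon0 + j + 1)`` with the origin at
the south-west corner (global default lat0=-90, lon0=-180).  Months are
indexed by (year, month) and handled internally as a monthly
:class:`pandas.PeriodIndex`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "FormatError",
    "IntegrityError",
    "GriddedField",
    "EmissionField",
    "VPDField",
    "OCISet",
    "RegionSeries",
    "month_index",
    "read_grid",
    "write_grid",
    "read_country_mask",
    "write_country_mask",
    "read_oci_csv",
    "write_oci_csv",
    "read_lookup",
    "write_lookup",
    "read_forecasts",
    "write_forecasts",
]

FORECAST_COLUMNS = [
    "fcr_id",
    "origin_year",
    "origin_month",
    "lead",
    "variant",
    "anomaly_pred",
    "emission_pred",
    "target_year",
    "target_month",
    "verifiable",
]

LOOKUP_COLUMNS = ["fcr_id", "lead", "oci_name", "oci_lag", "oci_r", "vpd_lag", "vpd_r"]


class FormatError(ValueError):
    """A file or container violates the expected layout (e.g. gappy months)."""


class IntegrityError(ValueError):
    """Internally inconsistent artifact (e.g. duplicate lookup rows)."""


def month_index(start_year: int, n_months: int, start_month: int = 1) -> pd.PeriodIndex:
    """Contiguous monthly PeriodIndex starting at (start_year, start_month)."""
    start = pd.Period(year=start_year, month=start_month, freq="M")
    return pd.period_range(start, periods=n_months, freq="M")


def _check_monthly(time: pd.PeriodIndex) -> None:
    if not isinstance(time, pd.PeriodIndex) or time.freqstr not in ("M", "ME"):
        raise FormatError("time axis must be a monthly PeriodIndex")
    if len(time) > 1:
        steps = np.diff(time.asi8)
        if not np.all(steps == 1):
            raise FormatError("time axis must be contiguous monthly")


@dataclass
class GriddedField:
    """A monthly field on an aligned 1-degree grid, shape (time, lat, lon)."""

    values: np.ndarray
    time: pd.PeriodIndex
    name: str = "field"
    units: str = ""
    lat0: float = -90.0
    lon0: float = -180.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise FormatError("values must be (time, lat, lon)")
        if self.values.shape[0] != len(self.time):
            raise FormatError("time axis length does not match values")
        _check_monthly(self.time)

    @property
    def n_lat(self) -> int:
        return self.values.shape[1]

    @property
    def n_lon(self) -> int:
        return self.values.shape[2]

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + 0.5 + np.arange(self.n_lat, dtype=float)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + 0.5 + np.arange(self.n_lon, dtype=float)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.time.year)

    def annual_sums(self, years: tuple[int, int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Calendar-year sums per cell.

        Returns ``(year_labels, sums)`` with ``sums`` of shape
        (n_years, n_lat, n_lon).  NaNs count as zero (missing emissions are
        reported as no burning).  ``years=(y0, y1)`` restricts to that
        inclusive window.
        """
        yr = self.time.year.values
        labels = np.unique(yr)
        if years is not None:
            y0, y1 = years
            if y0 < labels.min() or y1 > labels.max():
                raise FormatError(f"window {years} outside field span")
            labels = labels[(labels >= y0) & (labels <= y1)]
        vals = np.nan_to_num(self.values)
        out = np.empty((len(labels),) + self.values.shape[1:], dtype=float)
        for k, y in enumerate(labels):
            out[k] = vals[yr == y].sum(axis=0)
        return labels, out

    def select_window(self, years: tuple[int, int]) -> "GriddedField":
        mask = (self.time.year >= years[0]) & (self.time.year <= years[1])
        return type(self)(self.values[mask], self.time[mask], name=self.name,
                          units=self.units, lat0=self.lat0, lon0=self.lon0)


class EmissionField(GriddedField):
    """Monthly fire emissions per cell, Tg C/month; >= 0 where not missing."""

    def __init__(self, values, time, lat0: float = -90.0, lon0: float = -180.0,
                 name: str = "emissions", units: str = "Tg C month-1"):
        super().__init__(values, time, name=name, units=units, lat0=lat0, lon0=lon0)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise FormatError("emissions must be non-negative")


class VPDField(GriddedField):
    """Monthly vapor pressure deficit per cell, hPa."""

    def __init__(self, values, time, lat0: float = -90.0, lon0: float = -180.0,
                 name: str = "vpd", units: str = "hPa"):
        super().__init__(values, time, name=name, units=units, lat0=lat0, lon0=lon0)


@dataclass
class OCISet:
    """Named monthly ocean climate index series sharing one time axis.

    ``usable_names`` restricts which indices may be selected as predictors
    (some indices exist only to define others and are never selectable).
    """

    data: pd.DataFrame
    usable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_monthly(self.data.index)
        if not self.usable_names:
            self.usable_names = list(self.data.columns)
        unknown = set(self.usable_names) - set(self.data.columns)
        if unknown:
            raise IntegrityError(f"usable names not present: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def time(self) -> pd.PeriodIndex:
        return self.data.index

    def series(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass
class RegionSeries:
    """Per-region monthly series: summed emissions and mean VPD.

    ``emissions``: DataFrame (monthly PeriodIndex x fcr_id), Tg C/month,
    sums over member cells.  ``vpd``: same layout, hPa,
    cosine-latitude-area-weighted means (may be None).
    """

    emissions: pd.DataFrame
    vpd: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_monthly(self.emissions.index)
        if self.vpd is not None:
            if not self.emissions.index.equals(self.vpd.index):
                raise IntegrityError("emissions and VPD time axes differ")

    @property
    def fcr_ids(self) -> list[int]:
        return list(self.emissions.columns)

    @property
    def time(self) -> pd.PeriodIndex:
        return self.emissions.index


# ---------------------------------------------------------------------------
# gridded NetCDF I/O


def _field_to_dataset(fld: GriddedField) -> xr.Dataset:
    ds = xr.Dataset(
        {fld.name: (("time", "lat", "lon"), fld.values)},
        coords={
            "time": fld.time.to_timestamp(),
            "lat": fld.lat_centers,
            "lon": fld.lon_centers,
        },
    )
    ds[fld.name].attrs["units"] = fld.units
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    return ds


def write_grid(fld: GriddedField, path: str | Path) -> Path:
    """Write a gridded monthly field as NetCDF; returns the path."""
    path = Path(path)
    _field_to_dataset(fld).to_netcdf(path, engine="scipy")
    return path


def read_grid(path: str | Path, variable: str) -> GriddedField:
    """Read a gridded monthly field back; validates the monthly time axis."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not in {path}")
        da = ds[variable].load()
    time = pd.DatetimeIndex(da["time"].values).to_period("M")
    lat = np.asarray(da["lat"].values, dtype=float)
    lon = np.asarray(da["lon"].values, dtype=float)
    cls = {"emissions": EmissionField, "vpd": VPDField}.get(variable, GriddedField)
    kwargs = {} if cls is not GriddedField else {"name": variable}
    fld = cls(np.asarray(da.values, dtype=float), time,
              lat0=float(lat[0]) - 0.5, lon0=float(lon[0]) - 0.5, **kwargs)
    if variable not in ("emissions", "vpd"):
        fld.units = da.attrs.get("units", "")
    return fld


def write_country_mask(mask: np.ndarray, path: str | Path,
                       lat0: float = -90.0, lon0: float = -180.0) -> Path:
    path = Path(path)
    mask = np.asarray(mask, dtype=np.int32)
    n_lat, n_lon = mask.shape
    ds = xr.Dataset(
        {"country": (("lat", "lon"), mask)},
        coords={"lat": lat0 + 0.5 + np.arange(n_lat),
                "lon": lon0 + 0.5 + np.arange(n_lon)},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_country_mask(path: str | Path) -> np.ndarray:
    with xr.open_dataset(path, engine="scipy") as ds:
        if "country" not in ds:
            raise FormatError(f"variable 'country' not in {path}")
        return np.asarray(ds["country"].values, dtype=int)


# ---------------------------------------------------------------------------
# OCI CSV


def write_oci_csv(ocis: OCISet, path: str | Path) -> Path:
    path = Path(path)
    df = ocis.data.copy()
    out = pd.DataFrame({"year": df.index.year, "month": df.index.month})
    for name in df.columns:
        out[name] = df[name].values
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def read_oci_csv(path: str | Path, usable_names: list[str] | None = None) -> OCISet:
    df = pd.read_csv(path)
    if "year" not in df.columns or "month" not in df.columns:
        raise FormatError("OCI CSV must declare year and month columns")
    idx = pd.PeriodIndex.from_fields(year=df["year"], month=df["month"], freq="M")
    data = df.drop(columns=["year", "month"])
    data.index = idx
    return OCISet(data, usable_names=usable_names or list(data.columns))


# ---------------------------------------------------------------------------
# lookup tables (CSV + JSON carry identical content)


def _check_lookup(lookup: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOOKUP_COLUMNS if c not in lookup.columns]
    if missing:
        raise FormatError(f"lookup missing columns: {missing}")
    if lookup.duplicated(subset=["fcr_id", "lead"]).any():
        raise IntegrityError("duplicate (fcr_id, lead) lookup rows")
    return lookup[LOOKUP_COLUMNS]


def write_lookup(lookup: pd.DataFrame, path: str | Path) -> Path:
    """Serialize a predictor lookup; format chosen by suffix (.csv or .json)."""
    path = Path(path)
    lookup = _check_lookup(lookup)
    if path.suffix == ".json":
        records = lookup.to_dict(orient="records")
        for rec in records:  # JSON null for missing predictor entries
            for k, v in rec.items():
                if isinstance(v, float) and np.isnan(v):
                    rec[k] = None
        path.write_text(json.dumps(records, indent=1))
    else:
        lookup.to_csv(path, index=False, float_format="%.10g")
    return path


def read_lookup(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        lookup = pd.DataFrame(json.loads(path.read_text()))
        if lookup.empty:
            lookup = pd.DataFrame(columns=LOOKUP_COLUMNS)
    else:
        lookup = pd.read_csv(path)
    lookup = _check_lookup(lookup)
    lookup["oci_name"] = lookup["oci_name"].where(pd.notna(lookup["oci_name"]), None)
    return lookup.reset_index(drop=True)


# ---------------------------------------------------------------------------
# forecast records


def write_forecasts(records: pd.DataFrame, path: str | Path) -> Path:
    """Write forecast records sorted by (fcr_id, origin, lead)."""
    path = Path(path)
    missing = [c for c in FORECAST_COLUMNS if c not in records.columns]
    if missing:
        raise FormatError(f"forecast records missing columns: {missing}")
    out = records[FORECAST_COLUMNS].sort_values(
        ["fcr_id", "origin_year", "origin_month", "lead"], kind="mergesort"
    )
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def read_forecasts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FORECAST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"forecast records missing columns: {missing}")
    df["verifiable"] = df["verifiable"].astype(bool)
    return df
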
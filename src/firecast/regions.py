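"""Fire cohesive region (FCR) derivation and regional aggregation.

FCRs are the prediction units: blocks of 1-degree cells whose summed
emissions are large, temporally continuous and not dominated by a few
extreme years.  Candidate blocks are tested level by level from the finest
resolution (1 deg) up to the coarsest (8 deg), each coarser candidate
summing only the cells not already claimed at a finer level.  A passing
block that straddles a country border is split into one FCR per country
(keeping the level label).  After the 8-degree pass, leftover 8-degree
blocks with small but non-negligible mean emissions become relaxed "8r"
regions; whatever remains is low-fire and excluded from forecasting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EmissionField, IntegrityError, RegionSeries, VPDField, write_country_mask

__all__ = [
    "FCRCriteria",
    "FCRMap",
    "MultiResGrid",
    "build_multires_grid",
    "derive_e_min",
    "criteria_pass",
    "derive_fcrs",
    "aggregate_series",
    "write_fcr_map",
]

LEVELS = ("1", "2", "4", "8", "8r")


@dataclass
class FCRCriteria:
    """Thresholds for admitting a candidate block as an FCR.

    e_min: minimum mean annual emissions (Tg C/yr); if None it is derived
      from the data as the top_pct cutoff of per-cell mean annual totals.
    nonzero_year_frac: minimum fraction of years with nonzero emissions.
    cv_max: maximum coefficient of variation of the annual series.
    e_min_8r: relaxed mean-annual threshold for leftover 8-degree blocks.
    series_basis: 'annual' (default) or 'monthly' series for criteria 2-3.
    """

    e_min: float | None = None
    top_pct: float = 0.02
    nonzero_year_frac: float = 0.90
    cv_max: float = 2.0
    e_min_8r: float = 0.12
    series_basis: str = "annual"

    def __post_init__(self) -> None:
        if not (0 < self.nonzero_year_frac <= 1):
            raise ValueError("nonzero_year_frac must be in (0, 1]")
        for name in ("top_pct", "cv_max", "e_min_8r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.e_min is not None and self.e_min <= 0:
            raise ValueError("e_min must be > 0")
        if self.series_basis not in ("annual", "monthly"):
            raise ValueError("series_basis must be 'annual' or 'monthly'")


@dataclass
class MultiResGrid:
    """Aligned block tilings of the 1-degree grid at 2/4/8-degree levels.

    Each block is (row_slice, col_slice) into the 1-degree grid.  Blocks tile
    from the south-west corner; when 8 does not divide the grid size the last
    8-degree row (and column) is truncated to height (width) 4.
    """

    n_lat: int
    n_lon: int
    blocks: dict[str, list[tuple[slice, slice]]] = field(default_factory=dict)

    def level_blocks(self, level: str) -> list[tuple[slice, slice]]:
        return self.blocks[level]


def _tile_edges(n: int, size: int) -> list[tuple[int, int]]:
    edges = list(range(0, n, size))
    return [(e, min(e + size, n)) for e in edges]


def build_multires_grid(n_lat: int, n_lon: int) -> MultiResGrid:
    """Build the 1/2/4/8-degree block hierarchy over an n_lat x n_lon grid."""
    if n_lat % 4 or n_lon % 4:
        raise ValueError("grid dimensions must be divisible by 4")
    if n_lat % 8 not in (0, 4):
        raise ValueError("n_lat must be 0 or 4 modulo 8")
    if n_lon % 8 not in (0, 4):
        raise ValueError("n_lon must be 0 or 4 modulo 8")
    grid = MultiResGrid(n_lat, n_lon)
    for level, size in (("1", 1), ("2", 2), ("4", 4), ("8", 8)):
        rows = _tile_edges(n_lat, size)
        cols = _tile_edges(n_lon, size)
        grid.blocks[level] = [
            (slice(r0, r1), slice(c0, c1)) for r0, r1 in rows for c0, c1 in cols
        ]
    return grid


@dataclass
class FCRMap:
    """Cell-to-region assignment plus per-region metadata."""

    fcr_id: np.ndarray  # (n_lat, n_lon) int, 0 = unassigned (low fire)
    level: dict[int, str] = field(default_factory=dict)
    country: dict[int, int] = field(default_factory=dict)
    cells: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def ids(self) -> list[int]:
        return sorted(self.level)

    @property
    def n_regions(self) -> int:
        return len(self.level)

    def level_counts(self) -> dict[str, int]:
        out = {lv: 0 for lv in LEVELS}
        for lv in self.level.values():
            out[lv] += 1
        return out

    def region_table(self, field_: EmissionField | None = None,
                     dev_window: tuple[int, int] | None = None) -> pd.DataFrame:
        rows = []
        if field_ is not None:
            _, annual = field_.annual_sums(dev_window)
        for fid in self.ids:
            row = {"fcr_id": fid, "level": self.level[fid],
                   "country": self.country[fid], "n_cells": len(self.cells[fid])}
            if field_ is not None:
                ii = [c[0] for c in self.cells[fid]]
                jj = [c[1] for c in self.cells[fid]]
                row["mean_annual_emissions"] = float(annual[:, ii, jj].sum(axis=1).mean())
            rows.append(row)
        return pd.DataFrame(rows)


def derive_e_min(field_: EmissionField, top_pct: float = 0.02,
                 dev_window: tuple[int, int] | None = None) -> float:
    """Data-driven magnitude threshold (Tg C/yr).

    Nearest-rank cutoff: the k-th largest mean annual total among burning
    cells, k = ceil(top_pct * n).  With 100 cells of totals 1..100 and
    top_pct 0.02 this returns 99.
    """
    _, annual = field_.annual_sums(dev_window)
    means = annual.mean(axis=0).ravel()
    burning = np.sort(means[means > 0])[::-1]
    if burning.size == 0:
        raise ValueError("all-zero field: magnitude threshold undefined")
    k = max(1, int(np.ceil(top_pct * burning.size)))
    return float(burning[k - 1])


def criteria_pass(annual_series: np.ndarray, criteria: FCRCriteria,
                  e_min: float) -> tuple[bool, set[str]]:
    """Test one candidate series against the three admission criteria.

    Returns (passed, names of failed criteria).  ``annual_series`` is the
    calendar-year emission totals (Tg C/yr) of the candidate block.
    """
    annual_series = np.asarray(annual_series, dtype=float)
    if annual_series.size < 2:
        raise ValueError("need at least 2 years")
    failed: set[str] = set()
    mean = annual_series.mean()
    if not mean >= e_min:
        failed.add("magnitude")
    if (annual_series > 0).mean() < criteria.nonzero_year_frac:
        failed.add("continuity")
    if mean > 0:
        cv = annual_series.std(ddof=1) / mean
        if not cv < criteria.cv_max:
            failed.add("variability")
    else:
        failed.add("variability")
    return (not failed, failed)


def _split_by_country(cells: list[tuple[int, int]], mask: np.ndarray):
    by_country: dict[int, list[tuple[int, int]]] = {}
    for ij in cells:
        by_country.setdefault(int(mask[ij]), []).append(ij)
    return [by_country[c] for c in sorted(by_country)], sorted(by_country)


def derive_fcrs(field_: EmissionField, mask: np.ndarray, criteria: FCRCriteria,
                dev_window: tuple[int, int] | None = None) -> FCRMap:
    """Derive the FCR partition from the development-period emissions.

    Levels are processed in order 1, 2, 4, 8 on calendar-year sums restricted
    to ``dev_window``; at coarser levels a candidate's series sums only the
    member cells not already assigned.  Passing candidates spanning more than
    one country are split per country.  After level 8, unassigned 8-degree
    blocks with mean annual total above ``e_min_8r`` become level-8r FCRs.
    Ids are assigned level by level in row-major scan order from the
    south-west corner, starting at 1.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.shape != field_.values.shape[1:]:
        raise ValueError("country mask shape does not match field")
    _, annual = field_.annual_sums(dev_window)
    if criteria.series_basis == "monthly":
        series_cube = field_.select_window(dev_window).values if dev_window \
            else field_.values
        series_cube = np.nan_to_num(series_cube)
    else:
        series_cube = None
    e_min = criteria.e_min
    if e_min is None:
        e_min = derive_e_min(field_, criteria.top_pct, dev_window)

    grid = build_multires_grid(*mask.shape)
    assigned = np.zeros(mask.shape, dtype=bool)
    fcr_id = np.zeros(mask.shape, dtype=int)
    out = FCRMap(fcr_id)
    next_id = 1

    def admit(cells: list[tuple[int, int]], level: str) -> None:
        nonlocal next_id
        for group, code in zip(*_split_by_country(cells, mask)):
            for ij in group:
                fcr_id[ij] = next_id
                assigned[ij] = True
            out.level[next_id] = level
            out.country[next_id] = code
            out.cells[next_id] = list(group)
            next_id += 1

    for level in ("1", "2", "4", "8"):
        for rs, cs in grid.level_blocks(level):
            cells = [(i, j) for i in range(rs.start, rs.stop)
                     for j in range(cs.start, cs.stop) if not assigned[i, j]]
            if not cells:
                continue
            ii = [c[0] for c in cells]
            jj = [c[1] for c in cells]
            annual_series = annual[:, ii, jj].sum(axis=1)
            if criteria.series_basis == "monthly":
                test_series = series_cube[:, ii, jj].sum(axis=1)
                mean_ok = annual_series.mean() >= e_min
                nz_ok = (annual_series > 0).mean() >= criteria.nonzero_year_frac
                m = test_series.mean()
                cv_ok = m > 0 and test_series.std(ddof=1) / m < criteria.cv_max
                ok = mean_ok and nz_ok and cv_ok
            else:
                ok, _ = criteria_pass(annual_series, criteria, e_min)
            if ok:
                admit(cells, level)

    for rs, cs in grid.level_blocks("8"):
        cells = [(i, j) for i in range(rs.start, rs.stop)
                 for j in range(cs.start, cs.stop) if not assigned[i, j]]
        if not cells:
            continue
        ii = [c[0] for c in cells]
        jj = [c[1] for c in cells]
        if annual[:, ii, jj].sum(axis=1).mean() > criteria.e_min_8r:
            admit(cells, "8r")

    out.fcr_id = fcr_id
    return out


def cellwise_fcr_map(field_: EmissionField, mask: np.ndarray | None = None) -> FCRMap:
    """One level-1 FCR per burning cell, row-major ids from the south-west.

    A shortcut for experiments where every cell is its own prediction unit
    and the multi-resolution iteration is not of interest.
    """
    n_lat, n_lon = field_.values.shape[1:]
    if mask is None:
        mask = np.ones((n_lat, n_lon), dtype=int)
    fcr_id = np.zeros((n_lat, n_lon), dtype=int)
    out = FCRMap(fcr_id)
    next_id = 1
    totals = np.nan_to_num(field_.values).sum(axis=0)
    for i in range(n_lat):
        for j in range(n_lon):
            if totals[i, j] <= 0:
                continue
            fcr_id[i, j] = next_id
            out.level[next_id] = "1"
            out.country[next_id] = int(mask[i, j])
            out.cells[next_id] = [(i, j)]
            next_id += 1
    out.fcr_id = fcr_id
    return out


def aggregate_series(field_: EmissionField, vpd: VPDField | None,
                     fcr_map: FCRMap) -> RegionSeries:
    """Aggregate gridded fields to per-FCR series.

    Emissions: plain sum of member cells (missing treated as zero, matching
    how the inventory reports no burning).  VPD: cosine-latitude area
    weighted mean over member cells, missing excluded.
    """
    if vpd is not None and vpd.values.shape != field_.values.shape:
        raise ValueError("VPD and emission field shapes differ")
    n_time = field_.values.shape[0]
    lat_w = np.cos(np.deg2rad(field_.lat_centers))
    emis = {}
    vpd_out = {}
    for fid in fcr_map.ids:
        cells = fcr_map.cells[fid]
        if not cells:
            raise IntegrityError(f"FCR {fid} has no member cells")
        ii = [c[0] for c in cells]
        jj = [c[1] for c in cells]
        emis[fid] = np.nan_to_num(field_.values[:, ii, jj]).sum(axis=1)
        if vpd is not None:
            v = vpd.values[:, ii, jj]
            w = np.broadcast_to(lat_w[ii], (n_time, len(cells))).copy()
            w[~np.isfinite(v)] = 0.0
            v = np.nan_to_num(v)
            wsum = w.sum(axis=1)
            with np.errstate(invalid="ignore"):
                vpd_out[fid] = np.where(wsum > 0, (v * w).sum(axis=1) / wsum, np.nan)
    emis_df = pd.DataFrame(emis, index=field_.time)
    vpd_df = pd.DataFrame(vpd_out, index=field_.time) if vpd is not None else None
    return RegionSeries(emis_df, vpd_df)


_LEVEL_CODE = {lv: k + 1 for k, lv in enumerate(LEVELS)}


def write_fcr_map(fcr_map: FCRMap, path: str | Path,
                  table_path: str | Path | None = None,
                  field_: EmissionField | None = None,
                  dev_window: tuple[int, int] | None = None,
                  lat0: float = -90.0, lon0: float = -180.0) -> Path:
    """Write the FCR grid as NetCDF plus (optionally) the region CSV table."""
    import xarray as xr

    path = Path(path)
    n_lat, n_lon = fcr_map.fcr_id.shape
    level_grid = np.zeros((n_lat, n_lon), dtype=np.int32)
    for fid, cells in fcr_map.cells.items():
        for ij in cells:
            level_grid[ij] = _LEVEL_CODE[fcr_map.level[fid]]
    ds = xr.Dataset(
        {"fcr_id": (("lat", "lon"), fcr_map.fcr_id.astype(np.int32)),
         "level_code": (("lat", "lon"), level_grid)},
        coords={"lat": lat0 + 0.5 + np.arange(n_lat),
                "lon": lon0 + 0.5 + np.arange(n_lon)},
    )
    ds["level_code"].attrs["codes"] = "0=low-fire " + " ".join(
        f"{v}={k}" for k, v in _LEVEL_CODE.items())
    ds.to_netcdf(path, engine="scipy")
    if table_path is not None:
        fcr_map.region_table(field_, dev_window).to_csv(table_path, index=False)
    return path
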
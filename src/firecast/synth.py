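"""Synthetic gridded fire emissions, climate indices, VPD and country masks.

The generator plants recoverable structure so every downstream stage — region
derivation, anomaly transforms, predictor selection, ARIMAX fitting and skill
verification — can be exercised end to end without external data.  Each cell
carries a seasonal emission cycle with a configurable peak month, optional
linear trend, log-scale noise, optional zero inflation, and optionally a
lagged multiplicative coupling to one ocean climate index (OCI).  The planted
parameters are returned alongside the field so recovery can be scored.

Random-number contract: one root seed; every cell and every index draws from
its own independent substream (spawned by grid coordinates), so enlarging the
grid never reshuffles existing cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io import EmissionField, OCISet, VPDField, month_index

__all__ = [
    "BlockCoupling",
    "SynthConfig",
    "SynthTruth",
    "gen_oci_set",
    "gen_emission_field",
    "gen_vpd_field",
    "gen_country_mask",
    "seasonal_factors",
]


@dataclass(frozen=True)
class BlockCoupling:
    """Lagged OCI coupling planted on a rectangular cell block.

    ``rows``/``cols`` are half-open index ranges [start, stop).  The cell's
    log emissions gain ``coeff * oci[t - lag]``.
    """

    rows: tuple[int, int]
    cols: tuple[int, int]
    oci_name: str
    lag: int
    coeff: float

    def __post_init__(self) -> None:
        if not (1 <= self.lag <= 11):
            raise ValueError("coupling lag must be in 1..11 months")
        if not np.isfinite(self.coeff):
            raise ValueError("coupling coefficient must be finite")


@dataclass
class SynthConfig:
    """Parameters of the synthetic emission field.

    base_emission_map is the mean annual emission total per cell (Tg C/yr);
    trend_slope_map is a fractional change per year; noise_sd is the standard
    deviation of the log-scale multiplicative noise; zero_inflation_prob is
    the per-month probability of reporting zero emissions.
    """

    n_lat: int
    n_lon: int
    n_years: int
    start_year: int = 1997
    peak_month_map: int | np.ndarray = 8
    seasonal_concentration: float = 2.0
    base_emission_map: float | np.ndarray = 1.8
    trend_slope_map: float | np.ndarray = 0.0
    oci_coupling: list[BlockCoupling] = dc_field(default_factory=list)
    noise_sd: float = 0.3
    zero_inflation_prob: float | np.ndarray = 0.0
    seed: int = 0
    lat0: float = -8.0
    lon0: float = -180.0

    def __post_init__(self) -> None:
        if self.n_years < 4:
            raise ValueError("n_years must be >= 4")
        for name in ("peak_month_map", "base_emission_map",
                     "trend_slope_map", "zero_inflation_prob"):
            val = np.broadcast_to(np.asarray(getattr(self, name), dtype=float),
                                  (self.n_lat, self.n_lon)).copy()
            setattr(self, name, val)
        if np.any(self.base_emission_map < 0):
            raise ValueError("base emissions must be non-negative")
        if np.any((self.zero_inflation_prob < 0) | (self.zero_inflation_prob > 1)):
            raise ValueError("zero_inflation_prob must be in [0, 1]")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and non-negative")
        if self.seasonal_concentration < 0:
            raise ValueError("seasonal_concentration must be >= 0")

    @property
    def n_months(self) -> int:
        return 12 * self.n_years


@dataclass
class SynthTruth:
    """Planted parameters, mirrored from the config for recovery scoring."""

    couplings: list[BlockCoupling]
    trend_slope_map: np.ndarray
    peak_month_map: np.ndarray

    def coupling_at(self, i: int, j: int) -> BlockCoupling | None:
        for c in self.couplings:
            if c.rows[0] <= i < c.rows[1] and c.cols[0] <= j < c.cols[1]:
                return c
        return None


def _cell_rng(seed: int, i: int, j: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, i, j)))


def seasonal_factors(peak_month: int, concentration: float) -> np.ndarray:
    """Cosine-bump seasonal factors for months 1..12, renormalized to mean 1.

    ``((1 + cos(2*pi*(m - peak)/12))/2) ** concentration``; concentration 0
    gives a flat cycle, larger values a sharper burning season.
    """
    m = np.arange(1, 13)
    bump = ((1.0 + np.cos(2.0 * np.pi * (m - peak_month) / 12.0)) / 2.0) ** concentration
    return bump / bump.mean()


def gen_oci_set(n_indices: int, n_months: int, ar1_phi: float = 0.8,
                innovation_sd: float = 1.0, seed: int = 0,
                start_year: int = 1997) -> OCISet:
    """Zero-mean AR(1) monthly index series named OCI01..OCInn."""
    if not np.isfinite(ar1_phi) or not (0 <= ar1_phi < 1):
        raise ValueError("ar1_phi must be finite and in [0, 1)")
    if not np.isfinite(innovation_sd) or innovation_sd < 0:
        raise ValueError("innovation_sd must be finite and non-negative")
    if n_months < 24:
        raise ValueError("n_months must be >= 24")
    time = month_index(start_year, n_months)
    data = {}
    for k in range(n_indices):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, k)))
        eps = rng.normal(0.0, innovation_sd, size=n_months)
        x = np.empty(n_months)
        # stationary start so the whole series is mean-zero AR(1)
        scale0 = innovation_sd / np.sqrt(1 - ar1_phi**2) if ar1_phi > 0 else innovation_sd
        x[0] = rng.normal(0.0, scale0)
        for t in range(1, n_months):
            x[t] = ar1_phi * x[t - 1] + eps[t]
        data[f"OCI{k + 1:02d}"] = x
    return OCISet(pd.DataFrame(data, index=time))


def gen_emission_field(config: SynthConfig, ocis: OCISet) -> tuple[EmissionField, SynthTruth]:
    """Generate the gridded monthly emission field with planted structure.

    Per-cell monthly emissions:
    ``base/12 * seasonal(month) * max(0, 1 + trend*t_years) *
    exp(coeff*oci[t-lag] + noise)``, then zero-inflated.
    """
    known = set(ocis.names)
    for c in config.oci_coupling:
        if c.oci_name not in known:
            raise ValueError(f"coupling references unknown OCI {c.oci_name!r}")
    n_months = config.n_months
    time = month_index(config.start_year, n_months)
    if time[-1] > ocis.time[-1] or time[0] < ocis.time[0]:
        raise ValueError("OCI series must cover the emission time axis")

    months = time.month.values  # 1..12
    t_years = np.arange(n_months) / 12.0
    values = np.zeros((n_months, config.n_lat, config.n_lon))

    # coupling term per cell, resolved once; lag-shifted OCI values use any
    # spin-up months before the emission axis, zero-padded when absent
    coupling_term = {}
    for c in config.oci_coupling:
        shifted = ocis.data[c.oci_name].shift(c.lag).reindex(time)
        coupling_term[c] = c.coeff * shifted.fillna(0.0).values

    truth = SynthTruth(list(config.oci_coupling),
                       config.trend_slope_map.copy(),
                       config.peak_month_map.copy())

    for i in range(config.n_lat):
        for j in range(config.n_lon):
            base = config.base_emission_map[i, j] / 12.0
            seas = seasonal_factors(int(config.peak_month_map[i, j]),
                                    config.seasonal_concentration)[months - 1]
            trend = np.maximum(0.0, 1.0 + config.trend_slope_map[i, j] * t_years)
            logterm = np.zeros(n_months)
            cpl = truth.coupling_at(i, j)
            if cpl is not None:
                logterm = logterm + coupling_term[cpl]
            if config.noise_sd > 0:
                rng = _cell_rng(config.seed, i, j, stream=1)
                logterm = logterm + rng.normal(0.0, config.noise_sd, size=n_months)
            y = base * seas * trend * np.exp(logterm)
            p0 = config.zero_inflation_prob[i, j]
            if p0 > 0:
                rng0 = _cell_rng(config.seed, i, j, stream=2)
                y = np.where(rng0.random(n_months) < p0, 0.0, y)
            values[:, i, j] = y

    fld = EmissionField(values, time, lat0=config.lat0, lon0=config.lon0)
    return fld, truth


def gen_vpd_field(config: SynthConfig, fld: EmissionField, seed: int = 0,
                  shift: int = 1, scale: float = 1.0, noise_sd: float = 0.5,
                  base: float = 10.0, seasonal_amplitude: float = 5.0) -> VPDField:
    """VPD fields correlated with emissions at a short lead.

    ``vpd[t] = base + amp*seasonal + scale*anom[t + shift] + noise`` so that
    emissions at month t correlate most strongly with VPD at t - shift.
    Values are floored at 0 hPa.
    """
    if fld.values.shape[1:] != (config.n_lat, config.n_lon):
        raise ValueError("field shape does not match config")
    n_months = fld.values.shape[0]
    months = fld.time.month.values
    out = np.zeros_like(fld.values)
    for i in range(config.n_lat):
        for j in range(config.n_lon):
            y = np.nan_to_num(fld.values[:, i, j])
            # standardized per-calendar-month anomaly of the cell itself
            anom = np.zeros(n_months)
            for m in range(1, 13):
                sel = months == m
                mu, sd = y[sel].mean(), y[sel].std(ddof=1)
                anom[sel] = (y[sel] - mu) / sd if sd > 0 else 0.0
            lead = np.zeros(n_months)
            if shift > 0:
                lead[:n_months - shift] = anom[shift:]
            else:
                lead = anom
            seas = seasonal_factors(int(config.peak_month_map[i, j]), 1.0)[months - 1]
            v = base + seasonal_amplitude * (seas - 1.0) + scale * lead
            if noise_sd > 0:
                rng = _cell_rng(seed, i, j, stream=3)
                v = v + rng.normal(0.0, noise_sd, size=n_months)
            out[:, i, j] = np.maximum(v, 0.0)
    return VPDField(out, fld.time, lat0=fld.lat0, lon0=fld.lon0)


def gen_country_mask(n_lat: int, n_lon: int, n_countries: int, seed: int = 0) -> np.ndarray:
    """Integer country codes 1..n_countries as contiguous meridian strips."""
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    n_countries = min(n_countries, n_lon)
    edges = np.linspace(0, n_lon, n_countries + 1).round().astype(int)
    mask = np.empty((n_lat, n_lon), dtype=int)
    for c in range(n_countries):
        mask[:, edges[c]:edges[c + 1]] = c + 1
    return mask
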
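"""Bundled synthetic study scenarios.

``standard_scenario`` is the package's reference synthetic world: an 8x8
grid of strong, steadily burning cells (so every cell becomes its own
level-1 region), six AR(1) ocean climate indices with a one-year spin-up,
row-wise OCI couplings at lags spread over 1..6 months with log-scale noise
giving a coupling signal-to-noise ratio above 2, two countries, and VPD
fields leading emissions by one month.  An 18-year development window
mirrors the length of the historical training record the system is
designed around; the prediction window holds the remaining years.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EmissionField, OCISet, VPDField
from .regions import FCRCriteria
from .synth import (
    BlockCoupling,
    SynthConfig,
    SynthTruth,
    gen_country_mask,
    gen_emission_field,
    gen_oci_set,
    gen_vpd_field,
)

__all__ = ["Scenario", "standard_scenario"]


@dataclass
class Scenario:
    """A fully generated synthetic world plus its planted truth."""

    field: EmissionField
    vpd: VPDField
    mask: np.ndarray
    ocis: OCISet
    truth: SynthTruth
    config: SynthConfig
    criteria: FCRCriteria
    dev_window: tuple[int, int]
    prediction_window: tuple[int, int]


def standard_scenario(seed: int = 0, n_lat: int = 8, n_lon: int = 8,
                      dev_years: int = 18, pred_years: int = 2,
                      start_year: int = 1997, n_indices: int = 6,
                      coupling: float = 0.8, noise_sd: float = 0.35,
                      n_countries: int = 2) -> Scenario:
    """Build the reference synthetic scenario.

    Row ``i`` of the grid is coupled to index ``OCI(i % n_indices + 1)`` at
    lag ``i % 6 + 1`` months, so forecast skill decays lead by lead in
    aggregate.  With the defaults the coupling SNR is
    ``coupling * sd(OCI) / noise_sd ~ 2.3``.
    """
    n_years = dev_years + pred_years
    n_months = 12 * n_years
    ocis = gen_oci_set(n_indices, n_months + 12, ar1_phi=0.8, innovation_sd=0.6,
                       seed=seed, start_year=start_year - 1)
    couplings = [
        BlockCoupling(rows=(i, i + 1), cols=(0, n_lon),
                      oci_name=f"OCI{i % n_indices + 1:02d}",
                      lag=i % 6 + 1, coeff=coupling)
        for i in range(n_lat)
    ]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    peak = rng.integers(1, 13, size=(n_lat, n_lon))
    config = SynthConfig(
        n_lat=n_lat, n_lon=n_lon, n_years=n_years, start_year=start_year,
        peak_month_map=peak, seasonal_concentration=2.0,
        base_emission_map=2.0, trend_slope_map=0.0,
        oci_coupling=couplings, noise_sd=noise_sd,
        zero_inflation_prob=0.0, seed=seed,
    )
    field, truth = gen_emission_field(config, ocis)
    vpd = gen_vpd_field(config, field, seed=seed, shift=1, scale=1.0, noise_sd=0.5)
    mask = gen_country_mask(n_lat, n_lon, n_countries, seed=seed)
    criteria = FCRCriteria(e_min=0.5)
    return Scenario(field, vpd, mask, ocis, truth, config, criteria,
                    dev_window=(start_year, start_year + dev_years - 1),
                    prediction_window=(start_year + dev_years,
                                       start_year + n_years - 1))
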
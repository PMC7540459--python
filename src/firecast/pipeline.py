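"""End-to-end orchestration: regions -> transforms -> lookups -> forecasts -> skill.

The stages mirror the operational flow: derive fire cohesive regions from
development-period emissions, aggregate the gridded fields to regional
series, freeze climatologies and predictor/order lookup tables from the
development window, sweep walk-forward forecasts over the prediction
window for the requested model variants, and verify them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .evaluate import attach_observations, skill_report
from .forecast import (
    DEFAULT_LEADS,
    VARIANT_ORDER,
    VARIANTS,
    ForecastInputs,
    build_order_lookup,
    prepare_inputs,
    run_variant,
)
from .io import EmissionField, OCISet, RegionSeries, VPDField
from .regions import FCRCriteria, FCRMap, aggregate_series, derive_fcrs

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Artifacts of a full run."""

    fcr_map: FCRMap
    region_series: RegionSeries
    inputs: ForecastInputs
    order_lookups: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    forecasts: pd.DataFrame | None = None
    scored: pd.DataFrame | None = None
    report: pd.DataFrame | None = None


def run_pipeline(field: EmissionField, vpd: VPDField | None, mask: np.ndarray,
                 ocis: OCISet, criteria: FCRCriteria,
                 dev_window: tuple[int, int], prediction_window: tuple[int, int],
                 leads: tuple[int, ...] = DEFAULT_LEADS,
                 variants: tuple[str, ...] = tuple(VARIANT_ORDER),
                 fcr_map: FCRMap | None = None) -> PipelineResult:
    """Run every stage and return all intermediate artifacts.

    ``fcr_map`` can be supplied to skip region derivation (e.g. cell-wise
    experiment maps).
    """
    if dev_window[1] >= prediction_window[0]:
        raise ValueError("development window must precede the prediction window")
    if fcr_map is None:
        fcr_map = derive_fcrs(field, mask, criteria, dev_window)
    if fcr_map.n_regions == 0:
        raise ValueError("no fire cohesive regions found")
    region_series = aggregate_series(field, vpd, fcr_map)
    inputs = prepare_inputs(region_series, ocis, dev_window, leads)
    result = PipelineResult(fcr_map, region_series, inputs)

    frames = []
    for name in variants:
        spec = VARIANTS[name]
        order_lookup = None
        if spec.arima == "optimal":
            order_lookup = build_order_lookup(inputs, spec, leads)
            result.order_lookups[name] = order_lookup
        logger.info("running variant %s", name)
        frames.append(run_variant(inputs, spec, prediction_window, leads,
                                  order_lookup))
    result.forecasts = pd.concat(frames, ignore_index=True)
    result.scored = attach_observations(result.forecasts, region_series,
                                        inputs.clims)
    if len(result.scored):
        result.report = skill_report(result.scored)
    return result
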
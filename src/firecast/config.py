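"""Structured run configuration for the command-line interface."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .forecast import VARIANT_ORDER, VARIANTS

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated key set for a forecasting run.

    Either the synthetic block drives the generator (``simulate``), or the
    input paths point at existing NetCDF/CSV artifacts.  Windows are
    inclusive year ranges; the development window must precede the
    prediction window.
    """

    output_dir: str = "runs/out"
    # input paths (used when not synthetic)
    emissions_path: str | None = None
    vpd_path: str | None = None
    oci_path: str | None = None
    mask_path: str | None = None
    # synthetic scenario
    synthetic: bool = True
    seed: int = 0
    n_lat: int = 8
    n_lon: int = 8
    dev_years: int = 18
    pred_years: int = 2
    start_year: int = 1997
    # windows (derived from the synthetic block when None)
    dev_window: tuple[int, int] | None = None
    prediction_window: tuple[int, int] | None = None
    # region criteria
    e_min: float | None = None
    top_pct: float = 0.02
    nonzero_year_frac: float = 0.90
    cv_max: float = 2.0
    e_min_8r: float = 0.12
    # model setup
    leads: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    variants: tuple[str, ...] = tuple(VARIANT_ORDER)
    # engine options
    eq1_literal: bool = False
    sd_ddof: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.leads = tuple(int(x) for x in self.leads)
        self.variants = tuple(self.variants)
        if not self.leads or not set(self.leads) <= set(range(1, 7)):
            raise ValueError("leads must be a non-empty subset of 1..6")
        unknown = [v for v in self.variants if v not in VARIANTS]
        if unknown:
            raise ValueError(f"unknown variants: {unknown}")
        if self.dev_window is None:
            self.dev_window = (self.start_year, self.start_year + self.dev_years - 1)
        if self.prediction_window is None:
            self.prediction_window = (self.start_year + self.dev_years,
                                      self.start_year + self.dev_years
                                      + self.pred_years - 1)
        self.dev_window = tuple(int(v) for v in self.dev_window)
        self.prediction_window = tuple(int(v) for v in self.prediction_window)
        if self.dev_window[0] > self.dev_window[1]:
            raise ValueError("development window years out of order")
        if self.prediction_window[0] > self.prediction_window[1]:
            raise ValueError("prediction window years out of order")
        if self.dev_window[1] >= self.prediction_window[0]:
            raise ValueError("development window must precede prediction window")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
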
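"""Validated configuration for the co-culture simulator, renderer, segmenter and pipeline.

All concentrations are stored in molar units internally; reports print μM.
Rates are per hour (hazards) or per day (division/growth), as stated per field.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator


def default_titration(top_molar: float = 100e-6, n_dilutions: int = 19,
                      fold: float = 3.0) -> list[float]:
    """Three-fold serial dilution series plus the 0 M control, ascending.

    The default (19 dilutions below a 100 μM top dose, plus 0) gives 21
    concentrations per condition, filling a 384-well plate with
    3 constructs x 3 E:T ratios x duplicates = 378 wells.
    """
    doses = [top_molar / fold**k for k in range(n_dilutions + 1)]
    return sorted([0.0] + doses)


class SimulationConfig(BaseModel):
    """Generative parameters for one receptor construct in co-culture.

    The dynamics: per scan interval, each live target dies with hazard
    ``nonspecific_hazard + kill_max_hazard * hill(c) * rho_E`` where
    ``rho_E = E/(E+T)`` is the effector density; each live effector divides
    with per-day rate ``(prolif_baseline + prolif_max_rate * hill_p(c))``
    down-weighted by ``(1 - coupling_strength * kill_fraction)`` while
    killing is active; targets regrow logistically.
    """

    model_config = {"frozen": True}

    target_seed_count: int = Field(default=2000, gt=0)
    effector_to_target_ratios: tuple[float, ...] = (3.0, 1.0, 1.0 / 3.0)
    concentrations: tuple[float, ...] = tuple(default_titration())
    scan_interval: float = Field(default=2.0, gt=0)  # hours
    horizon: float = Field(default=96.0, gt=0)       # hours

    kill_EC50: float = Field(default=5e-8, gt=0)       # molar
    kill_max_hazard: float = Field(default=0.05, ge=0)  # per target per hour at rho_E = 1
    nonspecific_hazard: float = Field(default=0.001, ge=0)  # per target per hour at c = 0
    prolif_EC50: float = Field(default=1.7e-9, gt=0)   # molar
    prolif_max_rate: float = Field(default=0.45, ge=0)  # per effector per day
    prolif_baseline: float = Field(default=0.03, ge=0)  # per effector per day
    hill_slope_kill: float = Field(default=1.5, gt=0)
    hill_slope_prolif: float = Field(default=1.5, gt=0)
    coupling_strength: float = Field(default=1.0, ge=0, le=1)
    target_growth_rate: float = Field(default=1.0, ge=0)  # per day
    well_carrying_capacity: int = Field(default=8000, gt=0)  # cells

    red_area_per_dead_cell: float = Field(default=120.0, gt=0)   # pixels
    phase_area_per_target: float = Field(default=260.0, gt=0)    # pixels
    red_decay_per_hour: float = Field(default=0.0, ge=0)  # red signal clearance; 0 = persistent

    count_noise: Literal["none", "poisson"] = "poisson"
    rng_seed: int = 0

    @field_validator("effector_to_target_ratios")
    @classmethod
    def _ratios_positive(cls, v):
        if not v or any((not math.isfinite(r)) or r <= 0 for r in v):
            raise ValueError("effector_to_target_ratios must be positive and finite")
        return v

    @field_validator("concentrations")
    @classmethod
    def _concentrations_valid(cls, v):
        if not v:
            raise ValueError("concentrations must be non-empty")
        if any((not math.isfinite(c)) or c < 0 for c in v):
            raise ValueError("concentrations must be finite and >= 0")
        if list(v) != sorted(set(v)):
            raise ValueError("concentrations must be sorted and unique")
        return v

    @model_validator(mode="after")
    def _interval_divides_horizon(self):
        n = self.horizon / self.scan_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("scan_interval must divide horizon")
        if self.horizon < 2.0 + self.scan_interval:
            raise ValueError("horizon too short: no time points after the 2 h settling scan")
        return self


class SegmentationParams(BaseModel):
    """Object gating for the synthetic-frame segmenter.

    ``None`` thresholds trigger Otsu-style automatic selection per channel
    (with an empty-channel guard). Sizes are equivalent diameters in μm.
    """

    model_config = {"frozen": True}

    green_threshold: Optional[float] = None
    red_threshold: Optional[float] = None
    phase_threshold: Optional[float] = None
    effector_diameter_range: tuple[float, float] = (5.0, 15.0)
    min_circularity: float = Field(default=0.4, ge=0, le=1)

    @field_validator("effector_diameter_range")
    @classmethod
    def _diam_ok(cls, v):
        lo, hi = v
        if not (0 < lo < hi):
            raise ValueError("diameter bounds must be positive with lower < upper")
        return v


class RenderParams(BaseModel):
    """Geometry and photometry of the synthetic three-channel renderer."""

    model_config = {"frozen": True}

    shape: tuple[int, int] = (640, 640)
    microns_per_pixel: float = Field(default=1.25, gt=0)
    background: float = Field(default=8.0, ge=0)
    noise_sigma: float = Field(default=2.0, ge=0)
    green_intensity: float = Field(default=160.0, gt=0)
    red_intensity: float = Field(default=160.0, gt=0)
    phase_intensity: float = Field(default=140.0, gt=0)
    effector_diameter_um: tuple[float, float] = (6.0, 14.0)
    target_diameter_um: tuple[float, float] = (16.0, 24.0)
    dead_diameter_um: tuple[float, float] = (14.0, 22.0)
    # Optional stress-test hook: green dye dilution with division (per-generation halving).
    effector_intensity_scale: float = Field(default=1.0, gt=0)
    allow_overlap: bool = False
    max_place_tries: int = Field(default=200, gt=0)


class PlateSpec(BaseModel):
    """Plate layout: which constructs, ratios, doses and replicates to lay out."""

    model_config = {"frozen": True}

    plate_format: int = 384
    constructs: dict[str, dict] = Field(default_factory=lambda: {"SIM-TCR": {}})
    replicates: int = Field(default=2, gt=0)

    @field_validator("plate_format")
    @classmethod
    def _format_ok(cls, v):
        if v not in (96, 384):
            raise ValueError("plate_format must be 96 or 384")
        return v


class AnalysisParams(BaseModel):
    """Grid, lag and peak-time conventions for kinetics and dose-response."""

    model_config = {"frozen": True}

    grid_step: float = Field(default=6.0, gt=0)   # hours
    lag: float = Field(default=6.0, gt=0)          # hours; per-T-cell killing lag
    prolif_peak_time: float = 72.0                 # hours
    kill_peak_time: float = 48.0                   # hours
    rate_window: tuple[float, float] = (30.0, 72.0)
    min_doses_for_fit: int = Field(default=5, ge=2)

    @model_validator(mode="after")
    def _window_ok(self):
        lo, hi = self.rate_window
        if not lo < hi:
            raise ValueError("rate_window must satisfy lo < hi")
        if self.lag % self.grid_step:
            raise ValueError("lag must be a multiple of grid_step")
        return self


class ImagingModeParams(BaseModel):
    """How the from_images mode subsamples wells into rendered fields.

    ``field_fraction`` is the fraction of each well's latent cells drawn in
    the rendered field of view (a microscope images part of the well); counts
    derived from frames are therefore on the field scale, which cancels in
    every ratio-based readout.
    """

    model_config = {"frozen": True}

    field_fraction: float = Field(default=0.03, gt=0, le=1)
    frame_stride: int = Field(default=1, gt=0)  # render every Nth scan


class PipelineConfig(BaseModel):
    """Top-level run configuration (one structured YAML/TOML file)."""

    model_config = {"frozen": True}

    simulation: SimulationConfig = SimulationConfig()
    segmentation: SegmentationParams = SegmentationParams()
    rendering: RenderParams = RenderParams()
    plate: PlateSpec = PlateSpec()
    analysis: AnalysisParams = AnalysisParams()
    imaging_mode: ImagingModeParams = ImagingModeParams()


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML (.yml/.yaml) or TOML (.toml)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        raw = yaml.safe_load(text) or {}
    elif path.suffix.lower() == ".toml":
        import tomllib

        raw = tomllib.loads(text)
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r} (use YAML or TOML)")
    return PipelineConfig.model_validate(raw)


def config_hash(config: BaseModel) -> str:
    """Stable sha256 of a config, for run manifests."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
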
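"""Validated run configuration (YAML).

Unknown keys are rejected rather than ignored — a typo in a config file
must fail loudly, not silently run with defaults.  Out-of-range values
raise :class:`~imsiq.errors.ConfigError` naming the offending keys.
"""
from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

log = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    width_um: float = Field(300.0, gt=0)
    height_um: float = Field(300.0, gt=0)
    n_fibers: int = Field(25, ge=1)
    membrane_width_um: float = Field(5.0, ge=0)
    c_membrane: float = Field(500.0, ge=0)
    c_interior: float = Field(20.0, ge=0)
    c_background: float = Field(5.0, ge=0)
    revertant_fraction: float = Field(0.0, ge=0, le=1)
    revertant_boost: float = Field(10.0, ge=0)
    tissue_margin_um: float = Field(0.0, ge=0)
    resolution_um: float = Field(1.0, gt=0)


class AcquisitionConfig(_Strict):
    spot_um: float = Field(15.0, gt=0)
    scan_speed_um_s: float = Field(30.0, gt=0)
    acq_hz: float = Field(20.0, gt=0)
    line_pitch_um: float = Field(15.0, gt=0)
    offset_um: float = Field(7.5, ge=0)
    sensitivity_cps_per_ugkg: float = Field(5.0, gt=0)
    flicker_fraction: float = Field(0.05, ge=0)
    dark_cps: float = Field(240.0, ge=0)


class ReconstructionConfig(_Strict):
    target_pitch_um: float = Field(1.76, gt=0)
    fusion: str = Field("mean", pattern="^(mean|geometric)$")


class FilterConfig(_Strict):
    # Pipeline defaults: no pre-deconvolution smoothing (a blur the PSF does
    # not model biases membrane amplitudes down; TV handles the noise), and
    # enough iterations for thin-band restoration to plateau under the large
    # reconstruction PSF (RL approaches the true band amplitude from below,
    # slowly, when the PSF is ~3x the band width).
    gaussian_sigma_px: float = Field(0.0, ge=0)
    rl_iterations: int = Field(400, ge=1)
    rl_tv_lambda: float = Field(0.01, ge=0)


class CalibrationConfig(_Strict):
    # Table-level gelatine standards, blank first (ug/kg)
    standard_levels_ugkg: list[float] = Field(
        default_factory=lambda: [1.33, 16.78, 61.15, 241.08, 892.85, 3523.06]
    )
    standard_size_um: float = Field(150.0, gt=0)
    bracketed: bool = True
    drift_limit_percent: float = Field(10.0, gt=0)


class SegmentationConfig(_Strict):
    method: str = Field("kmeans", pattern="^(median|otsu|sauvola|phansalkar|kmeans|kmedians)$")
    k_clusters: int = Field(3, ge=2, le=9)
    keep_clusters: list[int] = Field(default_factory=lambda: [2, 3])
    window_px: int = Field(15, ge=3)


class RunConfig(_Strict):
    seed: int = 0
    n_replicates: int = Field(7, ge=1)
    output_dir: str = "imsiq_out"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)
    filtering: FilterConfig = Field(default_factory=FilterConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)


def build_run_config(data: dict) -> RunConfig:
    """Validate a nested dict into a RunConfig, reporting every bad key."""
    try:
        cfg = RunConfig.model_validate(data or {})
    except ValidationError as e:
        keys = ["/".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in e.errors()]
        raise ConfigError("invalid run configuration: " + "; ".join(keys)) from None
    defaults = RunConfig().model_dump()
    given = set((data or {}).keys())
    filled = [k for k in defaults if k not in given]
    if filled:
        log.info("config: defaults filled for %s", ", ".join(filled))
    return cfg


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return build_run_config(data)
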
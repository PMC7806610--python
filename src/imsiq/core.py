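"""Core containers shared across the pipeline.

Geometry convention (fixed to prevent orientation bugs): images are 2-D
arrays with 0-based pixel indices, row 0 at the top; ``x`` is the fast
(within-line) axis of the first ablation pass and maps to columns; ``y``
is the slow (line-pitch) axis and maps to rows.  All physical lengths are
in micrometres.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, UnitError

#: canonical unit tags
UNIT_CPS = "counts s-1"
UNIT_UGKG = "ug kg-1"
UNIT_MASK = "mask"

VALID_UNITS = (UNIT_CPS, UNIT_UGKG, UNIT_MASK)


@dataclass
class AcquisitionSpec:
    """Geometry and detector model of one laser-ablation pass.

    Defaults follow the high-resolution acquisition used for 300x300 um
    regions of interest: 15 um spot, 30 um/s scan speed at 20 Hz, line
    pitch equal to the spot size, second pass offset by half a pitch.

    The detector response is linear: expected intensity (cps) =
    ``sensitivity_cps_per_ugkg * concentration + dark_cps``.  Counts are
    Poisson over one acquisition window (1/acq_hz s) with multiplicative
    Gaussian flicker of relative SD ``flicker_fraction``.
    """

    spot_um: float = 15.0
    scan_speed_um_s: float = 30.0
    acq_hz: float = 20.0
    line_pitch_um: float = 15.0
    direction: str = "horizontal"
    offset_um: float = 0.0
    sensitivity_cps_per_ugkg: float = 5.0
    flicker_fraction: float = 0.05
    dark_cps: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_um <= 0:
            raise GeometryError(f"spot_um must be > 0, got {self.spot_um}")
        if self.scan_speed_um_s <= 0:
            raise GeometryError(f"scan_speed_um_s must be > 0, got {self.scan_speed_um_s}")
        if self.acq_hz <= 0:
            raise GeometryError(f"acq_hz must be > 0, got {self.acq_hz}")
        if self.line_pitch_um <= 0:
            raise GeometryError(f"line_pitch_um must be > 0, got {self.line_pitch_um}")
        if self.flicker_fraction < 0:
            raise GeometryError(f"flicker_fraction must be >= 0, got {self.flicker_fraction}")
        if self.direction not in ("horizontal", "vertical"):
            raise GeometryError(
                f"direction must be 'horizontal' or 'vertical', got {self.direction!r}"
            )

    @property
    def sample_spacing_um(self) -> float:
        """Along-scan distance between consecutive samples (speed / rate)."""
        return self.scan_speed_um_s / self.acq_hz

    @property
    def dwell_s(self) -> float:
        """Duration of one acquisition window."""
        return 1.0 / self.acq_hz

    def replace(self, **kw) -> "AcquisitionSpec":
        return replace(self, **kw)


@dataclass
class ElementalImage:
    """A 2-D elemental map with physical pixel size and a unit tag.

    ``values`` holds intensity (counts/s), concentration (ug/kg) or a
    0/1 mask, as declared by ``unit``.  ``provenance`` accumulates a
    human-readable processing history.
    """

    values: np.ndarray
    pixel_dx_um: float
    pixel_dy_um: float
    unit: str
    channel: str = "Gd158"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GeometryError(f"image must be 2-D, got shape {self.values.shape}")
        if self.pixel_dx_um <= 0 or self.pixel_dy_um <= 0:
            raise GeometryError(
                f"pixel pitches must be > 0, got dx={self.pixel_dx_um}, dy={self.pixel_dy_um}"
            )
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("image values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def width_um(self) -> float:
        return self.values.shape[1] * self.pixel_dx_um

    @property
    def height_um(self) -> float:
        return self.values.shape[0] * self.pixel_dy_um

    def require_unit(self, unit: str, what: str) -> None:
        if self.unit != unit:
            raise UnitError(f"{what} requires an image in {unit!r}, got {self.unit!r}")

    def evolve(self, values: np.ndarray, note: str, unit: str | None = None) -> "ElementalImage":
        """Return a copy with new values, appending ``note`` to the history."""
        return ElementalImage(
            values=np.asarray(values, dtype=np.float64),
            pixel_dx_um=self.pixel_dx_um,
            pixel_dy_um=self.pixel_dy_um,
            unit=self.unit if unit is None else unit,
            channel=self.channel,
            provenance=[*self.provenance, note],
        )
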
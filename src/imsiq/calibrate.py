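"""Matrix-matched external calibration and limit of quantification.

Standards are gelatine blocks spiked with known analyte mass fractions
(ug/kg), ablated under the same conditions as tissue.  The calibration is
an unweighted ordinary-least-squares line of mean intensity (cps) against
concentration; the lower limit of quantification (LLOQ) is five times the
standard deviation of the blank standard expressed in concentration units.
Runs are bracketed by a pre- and post-acquisition calibration whose slopes
are averaged, with the relative slope drift reported.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .core import UNIT_CPS, UNIT_UGKG, ElementalImage
from .errors import DegenerateInputError, FitError

log = logging.getLogger(__name__)


@dataclass
class CalibrationStandard:
    """One standard level: assigned concentration and its measured response."""

    concentration_ugkg: float
    mean_intensity_cps: float
    sd_intensity_cps: float = 0.0
    n_pixels: int = 1

    def __post_init__(self) -> None:
        if self.concentration_ugkg < 0:
            raise FitError("standard concentration must be >= 0")
        if self.n_pixels < 1:
            raise FitError("n_pixels must be >= 1")
        if self.sd_intensity_cps < 0:
            raise FitError("sd_intensity_cps must be >= 0")


@dataclass
class CalibrationModel:
    """OLS calibration line with linearity and quantification limit.

    ``lloq_ugkg`` is populated once blank pixels are available (see
    :func:`compute_lloq` / :func:`attach_lloq`); ``valid`` is False when
    the fitted slope is non-positive, in which case the model must not be
    applied.
    """

    slope: float
    intercept: float
    r_squared: float
    n_standards: int
    lloq_ugkg: float | None = None
    blank_sd_ugkg: float | None = None
    drift_percent: float | None = None

    @property
    def valid(self) -> bool:
        return self.slope > 0

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        from pathlib import Path

        return cls(**json.loads(Path(path).read_text()))


def fit_calibration(standards: list) -> CalibrationModel:
    """Unweighted OLS of mean intensity vs assigned concentration."""
    conc = np.array([s.concentration_ugkg for s in standards], dtype=np.float64)
    intens = np.array([s.mean_intensity_cps for s in standards], dtype=np.float64)
    if len(np.unique(conc)) < 2:
        raise FitError(
            f"need >= 2 standards with distinct concentrations, got {len(conc)}"
        )
    if np.ptp(intens) == 0:
        raise DegenerateInputError("zero intensity variance across standards")
    res = stats.linregress(conc, intens)
    model = CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_standards=len(conc),
    )
    if not model.valid:
        log.warning("calibration slope %.4g <= 0: model flagged unusable", model.slope)
    return model


def apply_calibration(img: ElementalImage, model: CalibrationModel) -> ElementalImage:
    """Convert an intensity image to concentration: c = (I - b) / a, clamped at 0."""
    img.require_unit(UNIT_CPS, "apply_calibration")
    if not model.valid:
        raise FitError(f"calibration model invalid (slope={model.slope})")
    conc = (img.values - model.intercept) / model.slope
    n_neg = int((conc < 0).sum())
    if n_neg:
        log.info("apply_calibration: clamped %d sub-blank pixels to 0", n_neg)
    conc = np.clip(conc, 0.0, None)
    return img.evolve(
        conc,
        f"calibrated: slope={model.slope:.6g} cps/(ug/kg), "
        f"intercept={model.intercept:.6g} cps, R2={model.r_squared:.6g}",
        unit=UNIT_UGKG,
    )


def compute_lloq(blank_pixels_ugkg) -> float:
    """LLOQ = 5 x sample SD (n-1 denominator) of blank pixel concentrations."""
    v = np.asarray(blank_pixels_ugkg, dtype=np.float64).ravel()
    if v.size < 2:
        raise FitError("compute_lloq needs >= 2 blank pixels")
    return float(5.0 * np.std(v, ddof=1))


def attach_lloq(model: CalibrationModel, blank_pixels_ugkg) -> CalibrationModel:
    """Record the blank SD and LLOQ on a fitted model (in place) and return it."""
    model.lloq_ugkg = compute_lloq(blank_pixels_ugkg)
    model.blank_sd_ugkg = model.lloq_ugkg / 5.0
    return model


def bracketed_calibration(
    pre: CalibrationModel,
    post: CalibrationModel,
    drift_limit_percent: float = 10.0,
) -> CalibrationModel:
    """Average pre-/post-acquisition calibrations and report slope drift.

    Drift is ``100 * |slope_pre - slope_post| / mean slope``; a drift above
    ``drift_limit_percent`` is logged as a warning but not rejected —
    judging acceptability is the operator's call.
    """
    if not (pre.valid and post.valid):
        raise FitError("both bracketing calibrations must be valid (slope > 0)")
    slope = 0.5 * (pre.slope + post.slope)
    drift = 100.0 * abs(pre.slope - post.slope) / slope
    if drift > drift_limit_percent:
        log.warning("calibration slope drift %.1f%% exceeds %.1f%%", drift, drift_limit_percent)
    lloqs = [m.lloq_ugkg for m in (pre, post) if m.lloq_ugkg is not None]
    blanks = [m.blank_sd_ugkg for m in (pre, post) if m.blank_sd_ugkg is not None]
    return CalibrationModel(
        slope=slope,
        intercept=0.5 * (pre.intercept + post.intercept),
        r_squared=min(pre.r_squared, post.r_squared),
        n_standards=pre.n_standards + post.n_standards,
        lloq_ugkg=float(np.mean(lloqs)) if lloqs else None,
        blank_sd_ugkg=float(np.mean(blanks)) if blanks else None,
        drift_percent=drift,
    )
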
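"""Synthetic muscle-section phantoms and simulated LA-ICP-MS acquisitions.

The phantom emulates a transverse muscle-fiber mosaic in which the analyte
(a lanthanide-tagged antibody against a sarcolemmal protein) concentrates in
a thin band along every fiber boundary, fiber interiors are near-null, and a
configurable fraction of "revertant" fibers carries boosted membrane signal.
Simulated line scans apply the laser-spot averaging and the Poisson-plus-
flicker detector noise of an ICP-MS, so every downstream stage of the
pipeline can be exercised and validated without instrument data.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import UNIT_UGKG, AcquisitionSpec, ElementalImage
from .errors import GeometryError, SizingError
from .linescan_io import LineScan, LineScanSet

#: assigned concentrations (ng/g == ug/kg) of the gelatine calibration
#: standards, blank first, and the relative SDs of their characterisation.
STANDARD_LEVELS_UGKG = (1.33, 16.78, 61.15, 241.08, 892.85, 3523.06)
STANDARD_SD_UGKG = (0.06, 0.15, 0.40, 1.86, 4.87, 13.53)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic muscle section.

    Concentrations are in ug/kg.  ``membrane_width_um`` is the full
    thickness of the sarcolemmal band drawn along each fiber boundary.
    ``revertant_fraction`` of fibers get their membrane concentration
    multiplied by ``revertant_boost`` (sporadic fibers with restored
    expression in an otherwise null section).
    """

    width_um: float = 300.0
    height_um: float = 300.0
    n_fibers: int = 25
    membrane_width_um: float = 5.0
    c_membrane: float = 500.0
    c_interior: float = 20.0
    c_background: float = 5.0
    revertant_fraction: float = 0.0
    revertant_boost: float = 10.0
    tissue_margin_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c_membrane", "c_interior", "c_background"):
            if getattr(self, name) < 0:
                raise SizingError(f"{name} must be >= 0")
        if not 0.0 <= self.revertant_fraction <= 1.0:
            raise SizingError("revertant_fraction must be in [0, 1]")
        if self.n_fibers < 1:
            raise SizingError("n_fibers must be >= 1")
        if self.membrane_width_um < 0:
            raise SizingError("membrane_width_um must be >= 0")
        tw = self.width_um - 2 * self.tissue_margin_um
        th = self.height_um - 2 * self.tissue_margin_um
        if tw <= 0 or th <= 0:
            raise SizingError("tissue_margin_um leaves no tissue area")
        # mean fiber diameter implied by the seed density must exceed the band width
        mean_diam = np.sqrt(tw * th / self.n_fibers)
        if self.membrane_width_um >= mean_diam:
            raise SizingError(
                f"membrane_width_um={self.membrane_width_um} is not smaller than the "
                f"mean fiber diameter {mean_diam:.1f} um implied by n_fibers={self.n_fibers}"
            )

    def replace(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


def generate_fiber_map(spec: PhantomSpec, resolution_um: float) -> np.ndarray:
    """Voronoi fiber mosaic on a pixel grid.

    Returns an integer label image where 0 is background (outside the
    tissue margin) and labels 1..n_fibers identify fibers, each the
    Voronoi cell of one seeded point.  Deterministic for a fixed seed.
    """
    if resolution_um <= 0:
        raise SizingError("resolution_um must be > 0")
    nx = int(round(spec.width_um / resolution_um))
    ny = int(round(spec.height_um / resolution_um))
    if nx < 8 or ny < 8:
        raise SizingError(
            f"resolution {resolution_um} um yields a {ny}x{nx} grid; need at least 8x8"
        )
    rng = np.random.default_rng(spec.seed)
    m = spec.tissue_margin_um
    seeds_x = rng.uniform(m, spec.width_um - m, spec.n_fibers)
    seeds_y = rng.uniform(m, spec.height_um - m, spec.n_fibers)

    xc = (np.arange(nx) + 0.5) * resolution_um
    yc = (np.arange(ny) + 0.5) * resolution_um
    xx, yy = np.meshgrid(xc, yc)
    tissue = (xx >= m) & (xx <= spec.width_um - m) & (yy >= m) & (yy <= spec.height_um - m)

    tree = cKDTree(np.column_stack([seeds_x, seeds_y]))
    pts = np.column_stack([xx[tissue], yy[tissue]])
    _, nearest = tree.query(pts)
    labels = np.zeros((ny, nx), dtype=np.int32)
    labels[tissue] = nearest.astype(np.int32) + 1
    return labels


def render_concentration_field(
    labels: np.ndarray, spec: PhantomSpec, resolution_um: float
) -> ElementalImage:
    """Paint ground-truth concentrations onto a fiber label image.

    Pixels within ``membrane_width_um / 2`` of any boundary between two
    different labels (fiber-fiber or fiber-background) take the membrane
    concentration; remaining fiber pixels the interior concentration;
    background the background concentration.  Membrane pixels belonging
    to a revertant fiber are boosted.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise GeometryError(f"labels must be 2-D, got shape {labels.shape}")

    # interface pixels: a tissue pixel whose 4-neighbourhood contains a different label
    diff = np.zeros(labels.shape, dtype=bool)
    diff[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    diff[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    diff[:-1, :] |= labels[:-1, :] != labels[1:, :]
    diff[1:, :] |= labels[1:, :] != labels[:-1, :]
    boundary = diff & (labels > 0)

    field = np.full(labels.shape, spec.c_background, dtype=np.float64)
    field[labels > 0] = spec.c_interior

    if boundary.any() and spec.membrane_width_um > 0:
        dist = ndimage.distance_transform_edt(~boundary, sampling=resolution_um)
        membrane = (dist <= spec.membrane_width_um / 2.0) & (labels > 0)
        rng = np.random.default_rng([spec.seed, 1])
        revertant = rng.random(spec.n_fibers) < spec.revertant_fraction
        c_mem = np.where(
            revertant, spec.c_membrane * spec.revertant_boost, spec.c_membrane
        )
        field[membrane] = c_mem[labels[membrane] - 1]

    return ElementalImage(
        values=field,
        pixel_dx_um=resolution_um,
        pixel_dy_um=resolution_um,
        unit=UNIT_UGKG,
        provenance=[f"phantom truth ({spec.n_fibers} fibers, seed {spec.seed})"],
    )


def _disk_kernel(diameter_px: float) -> np.ndarray:
    """Normalised top-hat disk; the idealised laser spot footprint."""
    r = diameter_px / 2.0
    n = int(np.ceil(diameter_px))
    if n % 2 == 0:
        n += 1
    c = n // 2
    y, x = np.ogrid[:n, :n]
    k = ((x - c) ** 2 + (y - c) ** 2 <= r * r).astype(np.float64)
    if k.sum() == 0:
        k[c, c] = 1.0
    return k / k.sum()


def _gaussian_kernel(diameter_px: float) -> np.ndarray:
    """Gaussian spot profile with FWHM equal to the spot diameter."""
    sigma = diameter_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    n = int(np.ceil(3 * diameter_px))
    if n % 2 == 0:
        n += 1
    c = n // 2
    y, x = np.ogrid[:n, :n]
    k = np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2 * sigma**2))
    return k / k.sum()


def simulate_linescans(
    truth: ElementalImage,
    acq: AcquisitionSpec,
    beam_profile: str = "tophat",
) -> LineScanSet:
    """Simulate one unidirectional ablation pass over a ground-truth field.

    For each line (spaced ``line_pitch_um`` along the slow axis, shifted by
    ``offset_um``) and each acquisition window, the expected concentration
    is the mean of the truth under the laser spot; expected counts per
    window are ``(sensitivity * c + dark) / acq_hz``; the recorded
    intensity is Poisson counts rescaled to cps with multiplicative
    Gaussian flicker, floored at zero.  Deterministic for a fixed seed.
    """
    truth.require_unit(UNIT_UGKG, "simulate_linescans")
    res = truth.pixel_dx_um
    if abs(truth.pixel_dy_um - res) > 1e-9:
        raise GeometryError("truth grid must have square pixels")
    if res > acq.spot_um / 2.0:
        raise GeometryError(
            f"truth pixel size {res} um must be <= spot_um/2 = {acq.spot_um / 2.0} um"
        )
    if truth.width_um < acq.spot_um or truth.height_um < acq.spot_um:
        raise GeometryError("truth grid smaller than one laser spot")

    d_px = acq.spot_um / res
    kernel = _gaussian_kernel(d_px) if beam_profile == "gaussian" else _disk_kernel(d_px)
    smoothed = ndimage.convolve(truth.values, kernel, mode="reflect")

    # fast/slow extents in the pass's own frame
    if acq.direction == "horizontal":
        fast_um, slow_um = truth.width_um, truth.height_um
    else:
        fast_um, slow_um = truth.height_um, truth.width_um

    dx = acq.sample_spacing_um
    n_samples = int(np.floor(fast_um / dx + 1e-9))
    pitch = acq.line_pitch_um
    line_pos = []
    k = 0
    while True:
        s = acq.offset_um + (k + 0.5) * pitch
        if s >= slow_um:
            break
        if s >= 0:
            line_pos.append(s)
        k += 1
    if n_samples < 1 or not line_pos:
        raise GeometryError("acquisition geometry yields no samples")

    fast_pos = (np.arange(n_samples) + 0.5) * dx
    rng = np.random.default_rng(acq.seed)
    dwell = acq.dwell_s
    times = (np.arange(n_samples) + 0.5) * dwell

    scans = []
    for i, s in enumerate(line_pos):
        if acq.direction == "horizontal":
            rows = np.full(n_samples, s / res - 0.5)
            cols = fast_pos / res - 0.5
        else:
            rows = fast_pos / res - 0.5
            cols = np.full(n_samples, s / res - 0.5)
        conc = ndimage.map_coordinates(
            smoothed, [rows, cols], order=1, mode="nearest"
        )
        lam = (acq.sensitivity_cps_per_ugkg * conc + acq.dark_cps) * dwell
        counts = rng.poisson(np.clip(lam, 0.0, None)).astype(np.float64)
        cps = counts / dwell
        if acq.flicker_fraction > 0:
            cps = cps * (1.0 + rng.normal(0.0, acq.flicker_fraction, n_samples))
        cps = np.clip(cps, 0.0, None)
        scans.append(
            LineScan(
                line_index=i,
                times_s=times.copy(),
                intensities_cps={truth.channel: cps},
            )
        )
    return LineScanSet(scans=scans, acq=acq, channel=truth.channel)


def generate_standard_block(
    concentration_ugkg: float,
    acq: AcquisitionSpec,
    size_um: tuple = (150.0, 150.0),
) -> LineScanSet:
    """Simulate ablation of a spatially uniform gelatine calibration standard."""
    if concentration_ugkg < 0:
        raise SizingError("concentration must be >= 0")
    w, h = size_um
    res = acq.spot_um / 4.0
    nx = int(round(w / res))
    ny = int(round(h / res))
    truth = ElementalImage(
        values=np.full((ny, nx), float(concentration_ugkg)),
        pixel_dx_um=res,
        pixel_dy_um=res,
        unit=UNIT_UGKG,
        provenance=[f"uniform standard {concentration_ugkg} ug/kg"],
    )
    return simulate_linescans(truth, acq)
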
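"""Raster assembly and super-resolution reconstruction (SRR).

A single ablation pass produces a strongly anisotropic raster: the fast
axis is sampled every ``scan_speed / acq_hz`` micrometres (1.5 um for the
high-resolution geometry) while the slow axis is sampled only once per
line pitch (15 um).  Fusing two orthogonal passes, the second offset by
half a line pitch, recovers an isotropic grid far finer than either pass
alone — each pass contributes its own fast axis.

The fusion operator is a per-pixel arithmetic mean of the two passes
resampled onto the common target grid (geometric mean optional).  Along a
pass's slow axis a sub-pixel falls inside exactly one physical ablation
swath, so resampling there uses nearest-line assignment; along the fast
axis it interpolates linearly.
"""
from __future__ import annotations

import logging

import numpy as np

from .core import UNIT_CPS, ElementalImage
from .errors import GeometryError
from .linescan_io import LineScanSet

log = logging.getLogger(__name__)


def assemble_raster(scans: LineScanSet, ragged_tolerance: int = 2) -> ElementalImage:
    """Stack line scans into a 2-D intensity raster in the pass's own frame.

    Row ``i`` is scan ``i``; column ``j`` is acquisition window ``j``.
    Pixel pitch is ``scan_speed/acq_hz`` along columns and the line pitch
    along rows.  Lines ragged by up to ``ragged_tolerance`` samples are
    padded with zeros (logged); anything more ragged is a geometry error.
    """
    rows = scans.intensities()
    lengths = [len(r) for r in rows]
    n = max(lengths)
    if n - min(lengths) > ragged_tolerance:
        raise GeometryError(
            f"line lengths range {min(lengths)}..{n}, exceeding ragged tolerance "
            f"{ragged_tolerance}"
        )
    if n != min(lengths):
        log.info("padding %d ragged lines to length %d", sum(l != n for l in lengths), n)
    grid = np.zeros((len(rows), n), dtype=np.float64)
    for i, r in enumerate(rows):
        grid[i, : len(r)] = r
    acq = scans.acq
    return ElementalImage(
        values=grid,
        pixel_dx_um=acq.sample_spacing_um,
        pixel_dy_um=acq.line_pitch_um,
        unit=UNIT_CPS,
        channel=scans.channel,
        provenance=[
            f"assembled raster: {len(rows)} lines x {n} samples, "
            f"dx={acq.sample_spacing_um} um, dy={acq.line_pitch_um} um, "
            f"direction={acq.direction}"
        ],
    )


def _resample_pass(
    img: ElementalImage,
    fast_t: np.ndarray,
    slow_t: np.ndarray,
    slow_offset_um: float,
) -> np.ndarray:
    """Sample a pass at target coordinates given in the pass's own frame.

    ``fast_t``/``slow_t`` are 2-D target-pixel coordinate grids (um) along
    the pass's fast and slow axes.  Nearest-line assignment along the slow
    axis, linear interpolation along the fast axis.
    """
    vals = img.values
    n_lines, n_samp = vals.shape
    # line centres sit at offset + (k + 0.5) * pitch
    li = np.rint((slow_t - slow_offset_um) / img.pixel_dy_um - 0.5).astype(int)
    li = np.clip(li, 0, n_lines - 1)
    cf = np.clip(fast_t / img.pixel_dx_um - 0.5, 0.0, n_samp - 1.0)
    c0 = np.floor(cf).astype(int)
    w = cf - c0
    c1 = np.clip(c0 + 1, 0, n_samp - 1)
    return vals[li, c0] * (1.0 - w) + vals[li, c1] * w


def srr_fuse(
    pass1: ElementalImage,
    pass2: ElementalImage,
    offset_um: float = 7.5,
    target_pitch_um: float | None = None,
    method: str = "mean",
) -> ElementalImage:
    """Fuse two orthogonal passes into an isotropic super-resolved image.

    ``pass1`` is taken in the common frame (fast axis = x).  ``pass2`` is
    the orthogonal pass in its own scan frame: its rows are ablation lines
    running along the common y axis, and its line positions are shifted by
    ``offset_um`` along x relative to pass 1's x origin.

    The default target pitch is ``line_pitch / 8`` floored at 1.5 um.
    Uniform inputs are preserved exactly, and the fused mean equals the
    mean of the two resampled passes by construction (arithmetic mean).
    """
    if method not in ("mean", "geometric"):
        raise GeometryError(f"unknown fusion method {method!r}")
    if pass1.unit != pass2.unit:
        raise GeometryError(f"pass units differ: {pass1.unit!r} vs {pass2.unit!r}")

    # common-frame extent covered by both passes; pass2's frame is transposed
    width = min(pass1.width_um, pass2.height_um)
    height = min(pass1.height_um, pass2.width_um)
    if width <= 0 or height <= 0:
        raise GeometryError("passes do not overlap")

    if target_pitch_um is None:
        target_pitch_um = max(min(pass1.pixel_dy_um, pass2.pixel_dy_um) / 8.0, 1.5)
    if target_pitch_um <= 0:
        raise GeometryError("target_pitch_um must be > 0")
    if target_pitch_um > min(pass1.pixel_dy_um, pass2.pixel_dy_um):
        raise GeometryError("target pitch must not exceed either pass's line pitch")

    nx = int(np.floor(width / target_pitch_um + 1e-9))
    ny = int(np.floor(height / target_pitch_um + 1e-9))
    if nx < 1 or ny < 1:
        raise GeometryError("target grid is empty")
    xs = (np.arange(nx) + 0.5) * target_pitch_um
    ys = (np.arange(ny) + 0.5) * target_pitch_um
    xg, yg = np.meshgrid(xs, ys)

    # pass 1: fast axis = x, slow = y, no offset
    a = _resample_pass(pass1, fast_t=xg, slow_t=yg, slow_offset_um=0.0)
    # pass 2: fast axis = y (its columns), slow = x, lines offset along x
    b = _resample_pass(pass2, fast_t=yg, slow_t=xg, slow_offset_um=offset_um)

    if method == "mean":
        fused = 0.5 * (a + b)
    else:
        fused = np.sqrt(np.clip(a, 0, None) * np.clip(b, 0, None))

    return ElementalImage(
        values=fused,
        pixel_dx_um=target_pitch_um,
        pixel_dy_um=target_pitch_um,
        unit=pass1.unit,
        channel=pass1.channel,
        provenance=[
            *pass1.provenance,
            f"SRR fusion ({method}) with orthogonal pass, offset {offset_um} um, "
            f"target pitch {target_pitch_um} um",
        ],
    )


def resample_passes(
    pass1: ElementalImage,
    pass2: ElementalImage,
    offset_um: float = 7.5,
    target_pitch_um: float = 1.76,
) -> tuple:
    """Return the two co-registered resampled grids used by :func:`srr_fuse`."""
    width = min(pass1.width_um, pass2.height_um)
    height = min(pass1.height_um, pass2.width_um)
    nx = int(np.floor(width / target_pitch_um + 1e-9))
    ny = int(np.floor(height / target_pitch_um + 1e-9))
    xs = (np.arange(nx) + 0.5) * target_pitch_um
    ys = (np.arange(ny) + 0.5) * target_pitch_um
    xg, yg = np.meshgrid(xs, ys)
    a = _resample_pass(pass1, fast_t=xg, slow_t=yg, slow_offset_um=0.0)
    b = _resample_pass(pass2, fast_t=yg, slow_t=xg, slow_offset_um=offset_um)
    return a, b
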
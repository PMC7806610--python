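"""Line-scan, image and mask I/O.

Line scans use one canonical delimited-text dialect: a single CSV file per
ablation pass, with one block per line scan, blocks separated by blank
lines, each block starting with a header row ``time_s,<channel>[,...]``.
Vendor exports vary widely, so the tool defines this one dialect and
leaves vendor conversion to import adapters.

Images and masks are 32-bit float single-channel TIFFs with a JSON sidecar
(``<path>.json``) carrying pixel size, unit, channel and provenance; the
reader is the exact inverse of the writer.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .core import VALID_UNITS, AcquisitionSpec, ElementalImage
from .errors import FormatError, GeometryError, MetadataError, SchemaError

log = logging.getLogger(__name__)


@dataclass
class LineScan:
    """One ablation line: acquisition times and per-channel intensities."""

    line_index: int
    times_s: np.ndarray
    intensities_cps: dict
    # channel -> 1-D array, all the same length as times_s

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.times_s.ndim != 1 or len(self.times_s) == 0:
            raise FormatError("times_s must be a non-empty 1-D sequence")
        if np.any(np.diff(self.times_s) <= 0):
            raise FormatError(f"line {self.line_index}: times must be strictly increasing")
        for ch, v in self.intensities_cps.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != self.times_s.shape:
                raise FormatError(
                    f"line {self.line_index}: channel {ch!r} length {len(v)} != "
                    f"time length {len(self.times_s)}"
                )
            if not np.all(np.isfinite(v)):
                raise FormatError(f"line {self.line_index}: non-finite intensity in {ch!r}")
            self.intensities_cps[ch] = v

    @property
    def channel_labels(self) -> list:
        return list(self.intensities_cps)

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class LineScanSet:
    """An ordered collection of line scans from one pass."""

    scans: list
    acq: AcquisitionSpec
    channel: str

    def __post_init__(self) -> None:
        if not self.scans:
            raise FormatError("a LineScanSet needs at least one scan")
        labels = self.scans[0].channel_labels
        for s in self.scans:
            if s.channel_labels != labels:
                raise SchemaError("all scans must share the same channel labels")
        if self.channel not in labels:
            raise SchemaError(
                f"active channel {self.channel!r} not among recorded channels {labels}"
            )

    def __len__(self) -> int:
        return len(self.scans)

    def intensities(self) -> list:
        """Per-line intensity arrays for the active channel."""
        return [s.intensities_cps[self.channel] for s in self.scans]


def write_linescan_csv(scans: LineScanSet, path) -> None:
    path = Path(path)
    channels = scans.scans[0].channel_labels
    with path.open("w") as fh:
        for i, s in enumerate(scans.scans):
            if i:
                fh.write("\n")
            fh.write("time_s," + ",".join(channels) + "\n")
            cols = [s.times_s] + [s.intensities_cps[c] for c in channels]
            for row in zip(*cols):
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_linescan_csv(path, acq: AcquisitionSpec, channel: str) -> LineScanSet:
    """Parse the canonical line-scan dialect.

    Negative intensities are clamped to zero (detector baseline artifacts)
    with the clamp count logged; non-numeric cells and non-monotone time
    columns raise typed errors rather than being skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    blocks: list = []
    current: list = []
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                if current:
                    blocks.append(current)
                    current = []
                continue
            current.append(line)
    if current:
        blocks.append(current)
    if not blocks:
        raise FormatError(f"{path}: no line-scan blocks found")

    scans = []
    n_clamped = 0
    for bi, block in enumerate(blocks):
        header = [h.strip() for h in block[0].split(",")]
        if not header or header[0] != "time_s":
            raise SchemaError(f"{path} block {bi}: header must start with 'time_s'")
        chans = header[1:]
        if channel not in chans:
            raise SchemaError(
                f"{path} block {bi}: channel {channel!r} not found; available: {chans}"
            )
        rows = []
        for ln in block[1:]:
            cells = ln.split(",")
            if len(cells) != len(header):
                raise FormatError(f"{path} block {bi}: row has {len(cells)} cells, "
                                  f"expected {len(header)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as e:
                raise FormatError(f"{path} block {bi}: non-numeric cell ({e})") from None
        if not rows:
            raise FormatError(f"{path} block {bi}: no data rows")
        arr = np.asarray(rows, dtype=np.float64)
        times = arr[:, 0]
        if np.any(np.diff(times) <= 0):
            raise FormatError(f"{path} block {bi}: time column not strictly increasing")
        intens = {}
        for j, ch in enumerate(chans):
            v = arr[:, j + 1]
            neg = v < 0
            n_clamped += int(neg.sum())
            intens[ch] = np.where(neg, 0.0, v)
        scans.append(LineScan(line_index=bi, times_s=times, intensities_cps=intens))
    if n_clamped:
        log.info("%s: clamped %d negative intensities to 0", path, n_clamped)
    return LineScanSet(scans=scans, acq=acq, channel=channel)


def write_image(img: ElementalImage, path) -> None:
    """32-bit float TIFF plus JSON sidecar with geometry/unit/provenance."""
    path = Path(path)
    if img.values.size == 0:
        raise GeometryError("refusing to write an empty image")
    tifffile.imwrite(path, img.values.astype(np.float32))
    sidecar = {
        "pixel_dx_um": img.pixel_dx_um,
        "pixel_dy_um": img.pixel_dy_um,
        "unit": img.unit,
        "channel": img.channel,
        "provenance": list(img.provenance),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path) -> ElementalImage:
    path = Path(path)
    side = Path(str(path) + ".json")
    if not side.exists():
        raise MetadataError(f"missing unit sidecar {side}")
    meta = json.loads(side.read_text())
    for key in ("pixel_dx_um", "pixel_dy_um", "unit"):
        if key not in meta:
            raise MetadataError(f"{side}: missing {key!r}")
    if meta["unit"] not in VALID_UNITS:
        raise MetadataError(f"{side}: unknown unit {meta['unit']!r}")
    values = tifffile.imread(path).astype(np.float64)
    return ElementalImage(
        values=values,
        pixel_dx_um=float(meta["pixel_dx_um"]),
        pixel_dy_um=float(meta["pixel_dy_um"]),
        unit=meta["unit"],
        channel=meta.get("channel", "Gd158"),
        provenance=list(meta.get("provenance", [])),
    )


def parse_run_config(path):
    """Read and validate a YAML run configuration (see :mod:`imsiq.config`)."""
    from .config import load_run_config

    return load_run_config(path)
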
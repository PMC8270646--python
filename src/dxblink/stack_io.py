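"""Image-stack, mask, and result I/O for diffracted X-ray blinking analysis.

Movies come off photon-counting detectors (e.g. Pilatus) as unsigned-integer
TIFF stacks, either multi-frame files or directories of per-frame images.
Frame timing is never trusted from TIFF tags; it is always supplied
explicitly (typically from the run configuration).

Pixel coordinates throughout the package are 0-based ``(row, col)``,
row-major.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Schema version written into every ensemble-summary JSON.
RESULTS_SCHEMA = "dxblink-results-1"

#: Column order of the per-pixel results table.
PIXEL_TABLE_COLUMNS = [
    "row",
    "col",
    "bin_size",
    "direction",
    "A",
    "gamma",
    "y",
    "residual",
    "accepted",
    "reason",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent image inputs."""


@dataclass
class FrameStack:
    """A time-ordered series of 2-D detector count images.

    Parameters
    ----------
    counts
        Array of shape ``(n_frames, rows, cols)``, non-negative integers
        (photon counts).
    frame_interval
        Time between frame starts, seconds.
    exposure
        Exposure per frame, seconds; must not exceed ``frame_interval``.
    mask
        Boolean validity mask, shape ``(rows, cols)``; ``True`` marks a
        usable pixel.  Defaults to all-valid.
    """

    counts: np.ndarray
    frame_interval: float = 0.05
    exposure: float = 0.042
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise FormatError(
                f"counts must be (frames, rows, cols); got shape {self.counts.shape}"
            )
        if self.counts.shape[0] == 0:
            raise FormatError("stack contains zero frames")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise FormatError(f"counts must be integer, got {self.counts.dtype}")
        if self.counts.min() < 0:
            raise FormatError("negative counts in stack")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure cannot exceed frame_interval")
        if self.mask is None:
            self.mask = np.ones(self.frame_shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frame_shape:
                raise FormatError(
                    f"mask shape {self.mask.shape} != frame shape {self.frame_shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_counts(self, counts: np.ndarray, mask: np.ndarray | None = None) -> "FrameStack":
        """Copy of this stack with new counts (and optionally a new mask)."""
        return replace(self, counts=counts, mask=mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameStack):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.frame_interval == other.frame_interval
            and self.exposure == other.exposure
            and np.array_equal(self.mask, other.mask)
        )


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry of a powder-diffraction setup.

    Attributes
    ----------
    wavelength
        X-ray wavelength in Angstrom (Cu K-alpha: 1.54).
    distance
        Sample-to-detector distance in mm.
    pixel_pitch
        Pixel pitch in micrometres (Pilatus: 172).
    beam_center
        Direct-beam position ``(row, col)`` in pixels.
    """

    wavelength: float
    distance: float
    pixel_pitch: float
    beam_center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    def ring_radius_px(self, two_theta_deg: float) -> float:
        """Radius in pixels of the Debye-Scherrer ring at scattering angle 2-theta."""
        r_mm = self.distance * np.tan(np.radians(two_theta_deg))
        return r_mm / (self.pixel_pitch * 1e-3)


def _widen_dtype(arr: np.ndarray) -> np.ndarray:
    """Widen counts to a lossless unsigned integer representation."""
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"expected integer pixel data, got {arr.dtype}")
    if arr.min() < 0:
        raise FormatError("negative counts in image data")
    if arr.dtype.itemsize < 8:
        return arr.astype(np.uint32 if arr.dtype.itemsize <= 4 else np.uint64)
    return arr


def read_stack(
    path: str | Path,
    frame_interval: float = 0.05,
    exposure: float = 0.042,
    mask: np.ndarray | None = None,
) -> FrameStack:
    """Read a movie from a multi-frame TIFF or a directory of per-frame TIFFs.

    Directory frames are taken in lexicographic (hence zero-padded numeric)
    order.  Timing always comes from the arguments, never from TIFF tags.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
        if not files:
            raise FormatError(f"no TIFF frames found in {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise FormatError(f"expected a frame stack, got shape {arr.shape}")
    arr = _widen_dtype(arr)
    return FrameStack(arr, frame_interval=frame_interval, exposure=exposure, mask=mask)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a multi-frame TIFF (counts only; timing lives in config)."""
    arr = stack.counts
    if arr.max(initial=0) <= np.iinfo(np.uint16).max:
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.uint32)
    tifffile.imwrite(Path(path), arr)


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a detector mask image; zero-valued pixels mark invalid regions.

    Module gaps of tiled photon-counting detectors (the intermodular
    rectangular areas) are the typical masked regions.
    """
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:  # collapse RGB(A) masks
        img = img[..., :3].max(axis=-1)
    if img.ndim != 2:
        raise FormatError(f"mask must be a 2-D image, got shape {img.shape}")
    if expected_shape is not None and img.shape != expected_shape:
        raise FormatError(f"mask shape {img.shape} != stack frame shape {expected_shape}")
    mask = img != 0
    logger.info("mask: %d invalid of %d pixels", int((~mask).sum()), mask.size)
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit TIFF (255 = valid, 0 = invalid)."""
    tifffile.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def write_results(
    pixel_table: pd.DataFrame,
    summary: dict,
    out_dir: str | Path,
    prefix: str = "dxb",
) -> tuple[Path, Path]:
    """Write the per-pixel fit table (CSV) and the ensemble summary (JSON).

    The CSV columns are fixed (see ``PIXEL_TABLE_COLUMNS``); coordinates are
    0-based (row, col) on the binned grid.  The JSON always carries a
    ``schema`` field so downstream readers can detect layout changes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{prefix}_pixels.csv"
    json_path = out_dir / f"{prefix}_summary.json"

    table = pixel_table.copy()
    for col in PIXEL_TABLE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[PIXEL_TABLE_COLUMNS]
    with open(csv_path, "w") as fh:
        fh.write("# dxblink per-pixel fits; coordinates 0-based (row, col), binned grid\n")
        table.to_csv(fh, index=False)

    payload = {"schema": RESULTS_SCHEMA, **summary}
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")
    return csv_path, json_path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
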
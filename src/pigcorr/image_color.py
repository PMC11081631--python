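"""Per-cell color extraction from bright-field z-stacks.

Each cell is photographed as a z-stack of RGB planes on a fixed canvas.
A circular region of interest (ROI) centered on the cell is averaged per
channel, the mean of all remaining pixels (the background) is subtracted,
and the background-subtracted intensities are aggregated across planes
into a per-cell color record (mean and SD of ΔR, ΔG, ΔB).

Pixel conventions: 0-based coordinates, ``(x, y) = (column, row)``,
origin at the top-left; a pixel belongs to the ROI disk when its center
satisfies ``(px - cx)**2 + (py - cy)**2 <= radius**2``.
"""

from __future__ import annotations

import glob as _glob
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RoiSpec",
    "ZStackImage",
    "CellColorRecord",
    "DEFAULT_ROI",
    "roi_plane_intensities",
    "subtract_background",
    "aggregate_planes",
    "measure_cell",
    "channel_correlation",
    "color_table",
    "read_zstack_tiff",
    "write_zstack_tiff",
    "read_zstack_png",
]

CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest on the image canvas.

    The instrument places each picked cell at a fixed position, so the
    ROI is defined by geometry, not segmentation.
    """

    center_x: float = 195.0
    center_y: float = 169.0
    radius: float = 50.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")

    def mask(self, height: int, width: int) -> np.ndarray:
        """Boolean disk-membership mask by the pixel-center rule."""
        ys = np.arange(height)[:, None]
        xs = np.arange(width)[None, :]
        return (xs - self.center_x) ** 2 + (ys - self.center_y) ** 2 <= self.radius**2

    def validate_within(self, height: int, width: int) -> None:
        """Raise if the disk is not fully inside the canvas (no warn-and-crop)."""
        if (
            self.center_x - self.radius < 0
            or self.center_y - self.radius < 0
            or self.center_x + self.radius > width - 1
            or self.center_y + self.radius > height - 1
        ):
            raise ValueError(
                f"ROI (center=({self.center_x}, {self.center_y}), radius={self.radius}) "
                f"extends beyond the {width}x{height} canvas"
            )


DEFAULT_ROI = RoiSpec()


@dataclass
class ZStackImage:
    """One cell's z-stack: ``planes`` with shape (n_planes, height, width, 3), 0-255."""

    planes: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.planes)
        if arr.ndim == 3:  # single plane
            arr = arr[None, ...]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(
                f"expected planes shaped (n_planes, H, W, 3), got {arr.shape}"
            )
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError("pixel intensities must lie in [0, 255]")
        self.planes = arr

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.planes.shape[1], self.planes.shape[2]


@dataclass
class CellColorRecord:
    """Background-subtracted mean color of one cell, aggregated across planes."""

    cell_id: str
    delta: np.ndarray  # (ΔR, ΔG, ΔB) mean across planes
    delta_sd: np.ndarray  # per-channel SD across planes
    n_planes_used: int
    saturated: bool = False  # any plane with >=1% ROI pixels at 255 (kept, flagged)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float).reshape(3)
        self.delta_sd = np.asarray(self.delta_sd, dtype=float).reshape(3)
        if np.any(np.abs(self.delta) > 255):
            raise ValueError(f"{self.cell_id}: delta outside [-255, 255]")
        if np.any(self.delta_sd < 0):
            raise ValueError(f"{self.cell_id}: negative delta SD")


def roi_plane_intensities(
    plane: np.ndarray, roi: RoiSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-channel intensity inside the ROI disk and over the background.

    Parameters
    ----------
    plane
        One RGB raster, shape (height, width, 3), intensities on 0-255.
    roi
        Disk specification; must lie fully inside the canvas.

    Returns
    -------
    (cell_mean, background_mean)
        Each a length-3 float array (R, G, B). The background is every
        pixel not in the disk, so the two pixel sets partition the canvas.
    """
    plane = np.asarray(plane)
    if plane.ndim != 3 or plane.shape[-1] != 3:
        raise ValueError(f"expected an RGB plane (H, W, 3), got shape {plane.shape}")
    h, w = plane.shape[:2]
    roi.validate_within(h, w)
    mask = roi.mask(h, w)
    if not mask.any():
        raise ValueError("ROI contains no pixel centers")
    if mask.all():
        raise ValueError("ROI covers the whole canvas; background is empty")
    pix = plane.reshape(-1, 3).astype(float)
    flat = mask.ravel()
    cell_mean = pix[flat].mean(axis=0)
    background_mean = pix[~flat].mean(axis=0)
    return cell_mean, background_mean


def subtract_background(cell_mean, background_mean) -> np.ndarray:
    """Per-channel Δ = cell ROI mean − background mean."""
    return np.asarray(cell_mean, dtype=float) - np.asarray(background_mean, dtype=float)


def aggregate_planes(
    deltas, cell_id: str = "", sd_mode: str = "population", saturated: bool = False
) -> CellColorRecord:
    """Aggregate per-plane Δ values into a per-cell record.

    ``sd_mode``: "population" divides by n (default), "sample" by n-1.
    """
    arr = np.asarray(list(deltas), dtype=float)
    if arr.size == 0:
        raise ValueError("aggregate_planes requires at least one plane")
    arr = arr.reshape(-1, 3)
    if sd_mode == "population":
        ddof = 0
    elif sd_mode == "sample":
        ddof = 1
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if ddof == 1 and arr.shape[0] < 2:
        raise ValueError("sample SD needs at least two planes")
    return CellColorRecord(
        cell_id=cell_id,
        delta=arr.mean(axis=0),
        delta_sd=arr.std(axis=0, ddof=ddof),
        n_planes_used=arr.shape[0],
        saturated=saturated,
    )


def measure_cell(
    stack: ZStackImage,
    roi: RoiSpec = DEFAULT_ROI,
    sd_mode: str = "population",
    saturation_fraction: float = 0.01,
) -> CellColorRecord:
    """Full per-cell color measurement: ROI means per plane, background
    subtraction per plane, then across-plane aggregation."""
    h, w = stack.shape
    roi.validate_within(h, w)
    mask = roi.mask(h, w)
    flat = mask.ravel()
    n_roi = int(flat.sum())
    deltas = []
    saturated = False
    for plane in stack.planes:
        pix = plane.reshape(-1, 3).astype(float)
        cell_mean = pix[flat].mean(axis=0)
        background_mean = pix[~flat].mean(axis=0)
        deltas.append(cell_mean - background_mean)
        if (pix[flat] >= 255).any(axis=1).sum() >= saturation_fraction * n_roi:
            saturated = True
    return aggregate_planes(
        deltas, cell_id=stack.cell_id, sd_mode=sd_mode, saturated=saturated
    )


def channel_correlation(records) -> pd.DataFrame:
    """3x3 Pearson matrix of (ΔR, ΔG, ΔB) across cells.

    Used as QC: on this instrument the three channels track each other
    almost perfectly (r > 0.99), which justifies collapsing them into a
    single brightness value. A zero-variance channel yields NaN entries
    (reported missing, never 0); requires at least three cells.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"channel correlation needs >=3 cells, got {len(records)}")
    x = np.stack([r.delta for r in records])  # (n_cells, 3)
    sd = x.std(axis=0)
    out = np.full((3, 3), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(3):
        for j in range(i + 1, 3):
            if sd[i] > 0 and sd[j] > 0:
                out[i, j] = out[j, i] = np.corrcoef(x[:, i], x[:, j])[0, 1]
            else:
                warnings.warn(
                    f"zero-variance channel {CHANNELS[i] if sd[i] == 0 else CHANNELS[j]}; "
                    "correlation undefined",
                    stacklevel=2,
                )
    return pd.DataFrame(out, index=CHANNELS, columns=CHANNELS)


def color_table(records) -> pd.DataFrame:
    """Serialize records to the per-cell color table schema."""
    rows = [
        {
            "cell_id": r.cell_id,
            "dR": r.delta[0],
            "dG": r.delta[1],
            "dB": r.delta[2],
            "sd_R": r.delta_sd[0],
            "sd_G": r.delta_sd[1],
            "sd_B": r.delta_sd[2],
            "n_planes": r.n_planes_used,
            "saturated": r.saturated,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def read_zstack_tiff(path: str, cell_id: str | None = None) -> ZStackImage:
    """Read a multi-page RGB TIFF (one page per z-plane)."""
    arr = tifffile.imread(path)
    if cell_id is None:
        cell_id = os.path.splitext(os.path.basename(path))[0]
    return ZStackImage(planes=arr, cell_id=cell_id)


def write_zstack_tiff(stack: ZStackImage, path: str) -> None:
    tifffile.imwrite(path, stack.planes.astype(np.uint8), photometric="rgb")


def read_zstack_png(pattern, cell_id: str = "") -> ZStackImage:
    """Read one plane per PNG; ``pattern`` is a glob or an explicit path list.

    Glob matches are sorted so the plane order follows the file naming.
    """
    import imageio.v3 as iio

    if isinstance(pattern, str):
        paths = sorted(_glob.glob(pattern))
    else:
        paths = list(pattern)
    if not paths:
        raise FileNotFoundError(f"no PNG planes match {pattern!r}")
    planes = np.stack([np.asarray(iio.imread(p))[..., :3] for p in paths])
    return ZStackImage(planes=planes, cell_id=cell_id)
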
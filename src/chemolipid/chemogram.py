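"""Calibrated chemogram container, region of interest, and image/report I/O.

A chemogram is a 2-D map of a coronary artery produced by a near-infrared
spectroscopy (NIRS) pullback: the x-axis is millimetres along the vessel,
the y-axis is degrees of catheter rotation, and a red-to-yellow colour scale
encodes the probability that lipid core plaque (LCP) is present at each
location.  Because the y-axis is a rotation angle, rows wrap cyclically at
the 0/360 degree seam: structures touching the top and bottom rows belong to
the same angular neighbourhood.

Coordinate conventions: row 0 = 0 degrees, column 0 = 0 mm; column extents in
mm are half-open intervals.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

from .errors import (
    CalibrationError,
    DimensionMismatchError,
    FormatError,
    RoiBoundsError,
)

__all__ = [
    "CalibrationConfig",
    "Chemogram",
    "RegionOfInterest",
    "read_chemogram",
    "write_chemogram",
    "roi_to_columns",
    "write_report",
    "read_report",
    "write_overlay",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Physical calibration of an exported chemogram raster.

    Parameters
    ----------
    mm_per_column
        Millimetres of pullback represented by one pixel column (> 0).
        Exported rasters do not carry a standard pixel pitch, so this is
        user-supplied configuration, never inferred from image metadata.
    pullback_speed_mm_per_s
        Informational only; automated pullbacks run at 0.5 mm/s.
    """

    mm_per_column: float
    pullback_speed_mm_per_s: float = 0.5

    def __post_init__(self) -> None:
        if not (self.mm_per_column > 0):
            raise CalibrationError(
                f"mm_per_column must be > 0, got {self.mm_per_column}"
            )


@dataclass(frozen=True)
class Chemogram:
    """An RGB chemogram raster with its physical calibration.

    ``pixels`` is an ``(H, W, 3)`` uint8 array; H rows span 360 degrees of
    catheter rotation, W columns span ``pullback_length_mm`` of pullback.
    """

    pixels: np.ndarray
    mm_per_column: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected (H, W, 3) RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("chemogram must have at least one row and column")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not (self.mm_per_column > 0):
            raise CalibrationError(
                f"mm_per_column must be > 0, got {self.mm_per_column}"
            )

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def degrees_per_row(self) -> float:
        """Angular height of one pixel row; rows tile the full 360 degrees."""
        return 360.0 / self.n_rows

    @property
    def pullback_length_mm(self) -> float:
        return self.n_cols * self.mm_per_column


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pullback interval ``[start_mm, end_mm)`` selected for analysis.

    Clinically this is typically the stented segment chosen by the physician.
    """

    start_mm: float
    end_mm: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_mm < self.end_mm):
            raise RoiBoundsError(
                f"require 0 <= start < end, got [{self.start_mm}, {self.end_mm})"
            )

    @property
    def length_mm(self) -> float:
        return self.end_mm - self.start_mm


def read_chemogram(path: str | Path, cal: CalibrationConfig) -> Chemogram:
    """Read a PNG/TIFF chemogram raster and attach calibration.

    Grayscale and paletted images are rejected: the pipeline needs the three
    colour channels (red for artifacts, green for lipid).
    """
    try:
        img = Image.open(path)
        img.load()
    except FileNotFoundError:
        raise
    except OSError as e:
        raise FormatError(f"cannot decode image {path}: {e}") from e
    if img.mode != "RGB":
        raise FormatError(
            f"chemogram must be a 3-channel RGB image, got mode {img.mode!r}"
        )
    return Chemogram(np.asarray(img, dtype=np.uint8), cal.mm_per_column)


def write_chemogram(chem: Chemogram, path: str | Path) -> None:
    """Write the raster losslessly (PNG or TIFF, by file extension)."""
    Image.fromarray(chem.pixels, mode="RGB").save(path)


def roi_to_columns(roi: RegionOfInterest, chem: Chemogram) -> tuple[int, int]:
    """Map an ROI in mm to a half-open pixel-column range ``[c0, c1)``.

    The range is the smallest column span covering the ROI:
    ``floor(start/mm_per_col)`` to ``ceil(end/mm_per_col)``.
    """
    if roi.end_mm > chem.pullback_length_mm + 1e-9:
        raise RoiBoundsError(
            f"ROI end {roi.end_mm} mm exceeds pullback length "
            f"{chem.pullback_length_mm} mm"
        )
    c0 = int(np.floor(roi.start_mm / chem.mm_per_column))
    c1 = int(np.ceil(roi.end_mm / chem.mm_per_column))
    c1 = min(c1, chem.n_cols)
    if c1 <= c0:
        raise RoiBoundsError(f"ROI maps to an empty column range [{c0}, {c1})")
    return c0, c1


def write_report(report: Mapping, path: str | Path) -> None:
    """Serialize an analysis report to JSON (lossless round-trip)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


_OVERLAY_COLOURS = {
    "lipid_combined": (255, 255, 255),
    "lipid_visible": (0, 255, 0),
    "lipid_hidden": (0, 200, 255),
    "artifact": (128, 128, 255),
}


def _contour(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a boolean mask, with cyclic row adjacency."""
    from scipy.ndimage import binary_erosion

    padded = np.vstack([mask[-1:], mask, mask[:1]])
    eroded = binary_erosion(padded, structure=np.ones((3, 3)), border_value=0)
    return mask & ~eroded[1:-1]


def write_overlay(
    chem: Chemogram, masks: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Write the chemogram with segmented regions outlined.

    ``masks`` maps labels (``lipid_combined``, ``artifact``, ...) to boolean
    arrays of the chemogram's shape; each mask's contour is drawn in a fixed
    colour on top of the original pixels.
    """
    out = chem.pixels.copy()
    for label, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != out.shape[:2]:
            raise DimensionMismatchError(
                f"mask {label!r} shape {mask.shape} != chemogram {out.shape[:2]}"
            )
        out[_contour(mask)] = _OVERLAY_COLOURS.get(label, (255, 0, 255))
    Image.fromarray(out, mode="RGB").save(path)
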
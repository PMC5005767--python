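"""Lipid Core Burden Index metrics, block chemograms, and lipid arcs.

The LCBI summarizes a chemogram segment as::

    LCBI = 1000 * (lipid pixels) / (valid pixels)

over the selected region, i.e. the fraction of viable pixels whose lipid
core plaque probability exceeds 0.6, scaled to 0-1000.  maxLCBI_2mm and
maxLCBI_4mm are the maximal LCBI over any 2 mm / 4 mm longitudinal window;
a published high-risk marker is maxLCBI_4mm >= 500 (this package prints the
value and renders no clinical verdict).

Two windowing modes are provided.  ``blocked`` partitions the region into
consecutive fixed tiles anchored at the region start — the display
convention of the commercial console.  ``sliding`` evaluates every window
position at a configurable stride and therefore never reports a smaller
maximum: lipid straddling a tile boundary is split by blocked mode but
captured whole by a sliding window.  This is the mechanism behind observed
discrepancies between blocked consoles and sliding re-analysis.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np

from .errors import DegenerateDataError, DimensionMismatchError, RoiBoundsError
from .masks import BinaryMask, longest_cyclic_run

__all__ = [
    "COLOUR_ORDER",
    "Block",
    "BlockChemogram",
    "LcbiReport",
    "classify_block",
    "block_chemogram",
    "lcbi_total",
    "max_lcbi_window",
    "max_lipid_arc",
    "valid_mask_from",
]

COLOUR_ORDER = ("red", "orange", "tan", "yellow")


def classify_block(p: float) -> str:
    """Map a block LCP probability to its display colour class.

    red: p < 0.57; orange: 0.57 <= p <= 0.84; tan: 0.84 < p <= 0.98;
    yellow: p > 0.98.  The published class intervals overlap at 0.84 and
    0.98; those boundary values are assigned to the lower class by fixed
    convention here.
    """
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if p < 0.57:
        return "red"
    if p <= 0.84:
        return "orange"
    if p <= 0.98:
        return "tan"
    return "yellow"


@dataclass(frozen=True)
class Block:
    """One 2 mm (by default) summary block of the block chemogram."""

    start_mm: float
    value: float  # 90th percentile of the block's pixel values
    colour_class: str | None
    partial: bool = False
    arc_deg: float | None = None


@dataclass(frozen=True)
class BlockChemogram:
    blocks: list[Block]
    block_length_mm: float = 2.0


@dataclass(frozen=True)
class LcbiReport:
    """Full LCBI report for one chemogram region."""

    lcbi_total: float
    max_lcbi_2mm: float
    max_lcbi_2mm_start_mm: float
    max_lcbi_4mm: float
    max_lcbi_4mm_start_mm: float
    mode: str
    roi_start_mm: float
    roi_end_mm: float
    lcbi_total_strict: float | None = None
    blocks: list[Block] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = [asdict(b) for b in self.blocks]
        return d


def valid_mask_from(
    artifact: BinaryMask, hidden: BinaryMask, policy: str = "reclaim"
) -> BinaryMask:
    """Build the viable-pixel mask used as the LCBI denominator.

    ``reclaim`` (default): all pixels except artifact pixels, but artifact
    pixels re-identified as hidden lipid are kept — they carry information.
    ``strict``: all pixels except every artifact pixel.
    """
    if artifact.shape != hidden.shape:
        raise DimensionMismatchError("artifact/hidden mask shapes differ")
    if policy == "reclaim":
        valid = ~artifact.values | hidden.values
    elif policy == "strict":
        valid = ~artifact.values
    else:
        raise ValueError(f"unknown valid-pixel policy {policy!r}")
    return BinaryMask(valid, "valid")


def _roi_slice(mask: np.ndarray, cols: tuple[int, int]) -> np.ndarray:
    return mask[:, cols[0] : cols[1]]


def lcbi_total(
    lipid_mask: BinaryMask, valid_mask: BinaryMask, roi_cols: tuple[int, int]
) -> float:
    """LCBI over the ROI columns: 1000 x lipid pixels / valid pixels."""
    if lipid_mask.shape != valid_mask.shape:
        raise DimensionMismatchError("lipid/valid mask shapes differ")
    lip = _roi_slice(lipid_mask.values & valid_mask.values, roi_cols)
    val = _roi_slice(valid_mask.values, roi_cols)
    n_valid = int(val.sum())
    if n_valid == 0:
        raise DegenerateDataError("no valid pixels in ROI; LCBI undefined")
    return 1000.0 * float(lip.sum()) / n_valid


def max_lcbi_window(
    lipid_mask: BinaryMask,
    valid_mask: BinaryMask,
    roi_cols: tuple[int, int],
    mm_per_column: float,
    window_mm: float,
    mode: Literal["blocked", "sliding"] = "sliding",
    stride_mm: float | None = None,
) -> tuple[float, float]:
    """Maximal LCBI over windows of ``window_mm``; returns (value, start_mm).

    ``blocked``: consecutive non-overlapping tiles anchored at the ROI start
    (a trailing partial tile is not a full-length segment and is skipped).
    ``sliding``: windows at every ``stride_mm`` (default: one pixel column).
    Ties go to the smallest start; windows containing no valid pixels are
    skipped.
    """
    if lipid_mask.shape != valid_mask.shape:
        raise DimensionMismatchError("lipid/valid mask shapes differ")
    c0, c1 = roi_cols
    win_cols = int(round(window_mm / mm_per_column))
    if win_cols < 1 or win_cols > c1 - c0:
        raise RoiBoundsError(
            f"window of {window_mm} mm ({win_cols} columns) does not fit the "
            f"ROI of {c1 - c0} columns"
        )
    lip = (lipid_mask.values & valid_mask.values).sum(axis=0).astype(np.float64)
    val = valid_mask.values.sum(axis=0).astype(np.float64)

    if mode == "blocked":
        starts = range(c0, c1 - win_cols + 1, win_cols)
    elif mode == "sliding":
        stride_cols = 1 if stride_mm is None else max(
            1, int(round(stride_mm / mm_per_column))
        )
        starts = range(c0, c1 - win_cols + 1, stride_cols)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best, best_start = -1.0, c0
    for s in starts:
        nv = val[s : s + win_cols].sum()
        if nv == 0:
            continue
        score = 1000.0 * lip[s : s + win_cols].sum() / nv
        if score > best:
            best, best_start = score, s
    if best < 0:
        raise DegenerateDataError("no window contains valid pixels")
    return best, best_start * mm_per_column


def block_chemogram(
    probability_map: np.ndarray,
    roi_cols: tuple[int, int],
    mm_per_column: float,
    block_mm: float = 2.0,
    percentile_method: str = "linear",
) -> BlockChemogram:
    """Summarize the ROI into 2 mm blocks of 90th-percentile values.

    ``probability_map`` holds per-pixel LCP probabilities in [0, 1]; NaN
    entries (pixels off the colour scale, e.g. artifacts) are ignored.  Each
    full tile gets a colour class from :func:`classify_block`; a trailing
    partial tile is reported with ``partial=True`` and no class.
    """
    c0, c1 = roi_cols
    block_cols = int(round(block_mm / mm_per_column))
    if block_cols < 1 or block_cols > c1 - c0:
        raise RoiBoundsError(f"block of {block_mm} mm does not fit the ROI")
    blocks: list[Block] = []
    s = c0
    while s < c1:
        e = min(s + block_cols, c1)
        partial = (e - s) < block_cols
        tile = probability_map[:, s:e]
        finite = tile[np.isfinite(tile)]
        if finite.size == 0:
            value, cls = float("nan"), None
        else:
            value = float(
                np.percentile(finite, 90, method=percentile_method)
            )
            cls = None if partial else classify_block(min(max(value, 0.0), 1.0))
        blocks.append(
            Block(start_mm=s * mm_per_column, value=value, colour_class=cls,
                  partial=partial)
        )
        s = e
    return BlockChemogram(blocks=blocks, block_length_mm=block_mm)


def max_lipid_arc(
    lipid_mask: BinaryMask,
    roi_cols: tuple[int, int],
    degrees_per_row: float,
    mm_per_column: float,
    block_mm: float = 2.0,
) -> list[tuple[float, float]]:
    """Maximal lipid arc per block: list of (block_start_mm, arc_degrees).

    For each column the arc is the angular extent of the longest
    cyclically-contiguous run of lipid rows (a run wrapping the 0/360 seam
    is a single run); each block reports the maximum over its columns.
    """
    c0, c1 = roi_cols
    block_cols = max(1, int(round(block_mm / mm_per_column)))
    col_runs = np.array(
        [longest_cyclic_run(lipid_mask.values[:, c]) for c in range(c0, c1)]
    )
    out: list[tuple[float, float]] = []
    s = c0
    while s < c1:
        e = min(s + block_cols, c1)
        arc = float(col_runs[s - c0 : e - c0].max()) * degrees_per_row
        out.append((s * mm_per_column, min(arc, 360.0)))
        s = e
    return out
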
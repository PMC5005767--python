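"""Artifact segmentation by Otsu thresholding of the adjusted red channel.

Guide-wire shadows and calcification shadows appear as contiguous near-black
regions on the chemogram (pixels without enough NIRS signal are rendered
black).  Since everywhere else the red channel is saturated by the
red-to-yellow colormap, the red-channel histogram is strongly bimodal and a
single Otsu threshold separates artifact from tissue.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .masks import BinaryMask, cyclic_label
from .preprocess import ChannelImage

__all__ = ["OtsuResult", "ArtifactRegion", "otsu_threshold", "detect_artifacts"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OtsuResult:
    """Threshold maximizing between-class variance on a 256-bin histogram.

    ``degenerate`` is set when the histogram has a single occupied bin, in
    which case ``threshold`` is that constant value and no meaningful
    two-class split exists.
    """

    threshold: int
    degenerate: bool


@dataclass(frozen=True)
class ArtifactRegion:
    """One connected artifact component (cyclic row adjacency)."""

    rows: np.ndarray
    cols: np.ndarray
    col_range: tuple[int, int]  # half-open [min, max+1)

    @property
    def area(self) -> int:
        return self.rows.size


def otsu_threshold(values: np.ndarray | ChannelImage) -> OtsuResult:
    """Otsu's threshold of an 8-bit image: maximize between-class variance.

    The split at threshold ``T`` puts values ``<= T`` in the dark class and
    values ``> T`` in the bright class.  All 255 candidate splits are scored
    by ``w0 * w1 * (mu0 - mu1)^2`` on the exact 256-bin histogram; ties are
    broken toward the smallest ``T``.  Deterministic by construction.
    """
    if isinstance(values, ChannelImage):
        values = values.values
    v = np.asarray(values)
    if v.size == 0:
        raise ValueError("cannot threshold an empty image")
    hist = np.bincount(v.astype(np.uint8).ravel(), minlength=256)
    occupied = np.nonzero(hist)[0]
    if occupied.size == 1:
        return OtsuResult(int(occupied[0]), degenerate=True)

    # Between-class variance at split t is (m0*W - w0*M)^2 / (w0*(W - w0))
    # up to a constant factor, with w0/m0 the count/intensity mass at or
    # below t.  Comparing these scores as exact integer fractions avoids
    # float near-ties, so the smallest-T tie rule is well defined.
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * np.arange(256, dtype=np.int64))
    W, M = int(w0[-1]), int(m0[-1])
    best_t = -1
    best_num, best_den = -1, 1  # score as exact fraction num/den
    for t in range(255):
        wt = int(w0[t])
        if wt == 0 or wt == W:
            continue
        a = int(m0[t]) * W - wt * M
        num, den = a * a, wt * (W - wt)
        if num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    return OtsuResult(best_t, degenerate=False)


def detect_artifacts(
    adjusted_red: ChannelImage,
    min_area_px: int = 8,
    cleanup: bool = False,
) -> tuple[BinaryMask, list[ArtifactRegion]]:
    """Segment dark artifact regions from the contrast-adjusted red channel.

    Pixels at or below the Otsu threshold are artifact candidates; connected
    components (8-connectivity, rows cyclic at the 0/360 degree seam) smaller
    than ``min_area_px`` are discarded as noise.  ``cleanup`` applies a
    single binary closing before component extraction (off by default).

    A degenerate (constant) channel yields an empty mask: with no intensity
    contrast there is no evidence of shadowing.
    """
    res = otsu_threshold(adjusted_red)
    shape = adjusted_red.shape
    if res.degenerate:
        log.info("detect_artifacts: degenerate histogram, returning empty mask")
        return BinaryMask(np.zeros(shape, dtype=bool), "artifact"), []

    cand = adjusted_red.values <= res.threshold
    if cleanup:
        padded = np.vstack([cand[-1:], cand, cand[:1]])
        padded = ndimage.binary_closing(padded, structure=np.ones((3, 3)))
        cand = padded[1:-1]

    labels, n = cyclic_label(cand)
    mask = np.zeros(shape, dtype=bool)
    regions: list[ArtifactRegion] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_area_px:
            continue
        mask[rows, cols] = True
        regions.append(
            ArtifactRegion(
                rows=rows,
                cols=cols,
                col_range=(int(cols.min()), int(cols.max()) + 1),
            )
        )
    return BinaryMask(mask, "artifact"), regions
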
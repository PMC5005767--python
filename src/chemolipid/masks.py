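"""Binary masks and connected components on the cyclic chemogram grid.

The chemogram's vertical axis is catheter rotation, so row 0 and row H-1 are
angular neighbours: every connectivity operation here uses 8-connectivity in
the plane plus wrap-around across the 0/360 degree seam.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionMismatchError

__all__ = [
    "MaskLabel",
    "BinaryMask",
    "cyclic_label",
    "longest_cyclic_run",
]

# Recognised mask roles; lipid_hidden is always a subset of artifact.
MaskLabel = ("artifact", "lipid_visible", "lipid_hidden", "lipid_combined", "valid")


@dataclass(frozen=True)
class BinaryMask:
    """A boolean per-pixel mask with a semantic label."""

    values: np.ndarray  # (H, W) bool
    label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        if v.ndim != 2:
            raise DimensionMismatchError(f"mask must be 2-D, got shape {v.shape}")
        if self.label not in MaskLabel:
            raise ValueError(f"unknown mask label {self.label!r}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area(self) -> int:
        return int(self.values.sum())


_EIGHT = np.ones((3, 3), dtype=int)


def cyclic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label connected components with 8-connectivity and cyclic rows.

    Returns ``(labels, n)`` like :func:`scipy.ndimage.label`, but components
    touching across the top/bottom seam are merged into one label.  Labels
    are renumbered 1..n in order of first appearance.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0 or mask.shape[0] < 2:
        return labels, n

    # Union labels adjacent across the seam (row H-1 <-> row 0, 8-connected).
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    top, bot = labels[0], labels[-1]
    W = mask.shape[1]
    for c in range(W):
        if bot[c] == 0:
            continue
        for cc in (c - 1, c, c + 1):
            if 0 <= cc < W and top[cc] != 0:
                ra, rb = find(bot[c]), find(top[cc])
                if ra != rb:
                    parent[rb] = ra

    roots = np.array([find(i) for i in range(n + 1)])
    # compact renumbering, preserving first-appearance order
    remap = np.zeros(n + 1, dtype=labels.dtype)
    nxt = 0
    for i in range(1, n + 1):
        r = roots[i]
        if remap[r] == 0:
            nxt += 1
            remap[r] = nxt
    return remap[roots[labels]], nxt


def longest_cyclic_run(col: np.ndarray) -> int:
    """Length of the longest cyclically-contiguous run of True in a vector.

    A run crossing the end/start boundary counts as one run; an all-True
    vector yields its full length.
    """
    col = np.asarray(col, dtype=bool)
    n = col.size
    if n == 0 or not col.any():
        return 0
    if col.all():
        return n
    # Break the circle at a False position, then take the max linear run;
    # doubling handles wrap-around without special cases.
    doubled = np.concatenate([col, col])
    best = cur = 0
    for v in doubled:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return min(best, n)
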
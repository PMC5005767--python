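"""Channel decomposition and saturating contrast stretch.

Artifacts (guide-wire and calcification shadows) appear as near-black holes
in every channel but are most cleanly separated on the red channel, because
the red component is saturated everywhere the colormap has data.  Lipid, on
the red-to-yellow scale, is encoded almost entirely by the green channel.
Each channel is therefore analysed as its own grayscale image after a
contrast stretch that saturates 1% of the pixel mass at each intensity
extreme.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chemogram import Chemogram

__all__ = ["ChannelImage", "split_channels", "adjust_intensity"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChannelImage:
    """A single 8-bit grayscale channel of a chemogram."""

    values: np.ndarray  # (H, W) uint8
    channel_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"channel image must be 2-D, got shape {v.shape}")
        if v.dtype != np.uint8:
            if v.min() < 0 or v.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            v = np.round(v).astype(np.uint8)
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def split_channels(
    chem: Chemogram,
) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Split an RGB chemogram into its red, green and blue channel images."""
    px = chem.pixels
    return (
        ChannelImage(px[:, :, 0], "red"),
        ChannelImage(px[:, :, 1], "green"),
        ChannelImage(px[:, :, 2], "blue"),
    )


def adjust_intensity(
    img: ChannelImage, low_frac: float = 0.01, high_frac: float = 0.01
) -> ChannelImage:
    """Linear contrast stretch saturating the intensity tails.

    Values at or below the ``low_frac`` quantile map to 0, values at or above
    the ``1 - high_frac`` quantile map to 255, and the interior is rescaled
    linearly (quantiles by linear interpolation of order statistics).  A
    constant image has no contrast to stretch and is returned unchanged.
    """
    if not (0 <= low_frac and 0 <= high_frac and low_frac + high_frac < 1):
        raise ValueError(
            f"need 0 <= low_frac, high_frac and low+high < 1, "
            f"got {low_frac}, {high_frac}"
        )
    v = img.values.astype(np.float64)
    lo, hi = np.quantile(v, [low_frac, 1.0 - high_frac], method="linear")
    if hi <= lo:
        log.info(
            "adjust_intensity: degenerate %s channel (quantiles %g == %g), "
            "returning input unchanged",
            img.channel_name,
            lo,
            hi,
        )
        return img
    out = np.clip((v - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return ChannelImage(np.round(out).astype(np.uint8), img.channel_name)
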
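"""Synthetic chemogram generator with full ground truth.

Clinical chemograms come from proprietary consoles and the patient data
behind published studies is not distributable, so every pipeline stage is
validated against scenes generated here: a latent lipid-core-plaque (LCP)
probability map in [0, 1], rendered through an invertible red-to-yellow
colormap, with black shadow artifacts painted on top and per-pixel noise.
The generator returns the latent map and exact masks, so segmentation and
LCBI accuracy can be scored against known truth.

What is emulated: the red-to-yellow probability scale; sharp-shouldered
lipid pools (real pools look near-binary on the display colormap, so blobs
are super-Gaussian bumps, not plain Gaussians); a guide-wire shadow band
spanning the whole pullback at a ~15-30 degree height; localized
calcification shadows over lipid; a weak residual green signal under
shadows covering lipid (this is what the hidden-lipid stage recovers);
additive clipped Gaussian pixel noise.  Not emulated: the proprietary
spectral prediction model, speckle or motion artifacts, display
anti-aliasing — conclusions from these scenes are about the segmentation
and metric machinery, not about spectroscopy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemogram import Chemogram
from .masks import BinaryMask
from . import metrics as _metrics

__all__ = [
    "LipidBlob",
    "ArtifactBand",
    "SceneSpec",
    "SyntheticTruth",
    "colormap_forward",
    "colormap_inverse",
    "generate_chemogram",
    "generate_paired_dataset",
    "random_scene",
]

#: probability above which a pixel counts as lipid core plaque (LCBI cut)
LCP_PROBABILITY_CUT = 0.6


@dataclass(frozen=True)
class LipidBlob:
    """A super-Gaussian lipid pool: p = peak * exp(-(d^2)^sharpness).

    ``d`` is the elliptical normalized distance from the centre; rows are
    measured cyclically (a blob may wrap the 0/360 degree seam).  Higher
    ``sharpness`` gives a flatter top and steeper shoulder.
    """

    center_row: float
    center_col: float
    radius_rows: float
    radius_cols: float
    peak: float = 0.95
    sharpness: float = 12.0


@dataclass(frozen=True)
class ArtifactBand:
    """A dark shadow rectangle; ``row_start > row_end`` wraps the seam."""

    row_start: int
    row_end: int  # exclusive; wraps if <= row_start
    col_start: int
    col_end: int  # exclusive
    darkness: float = 10.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic chemogram scene."""

    H: int = 360
    W: int = 200
    mm_per_column: float = 0.25
    blobs: list[LipidBlob] = field(default_factory=list)
    artifact_bands: list[ArtifactBand] = field(default_factory=list)
    noise_sd: float = 8.0
    # Residual green gray levels per unit lipid probability leaking through a
    # shadow.  42 puts the delta-threshold crossing (default delta 25) at the
    # 0.6 LCP probability cut: the regime in which mode-plus-delta recovery
    # can agree with the probability-defined truth (see methods note).
    lipid_bleed: float = 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H < 1 or self.W < 1:
            raise ValueError("scene must have positive dimensions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for b in self.blobs:
            if not (0 <= b.center_row < self.H and 0 <= b.center_col < self.W):
                raise ValueError(f"blob centre {b} outside image bounds")
            if b.radius_rows <= 0 or b.radius_cols <= 0:
                raise ValueError("blob radii must be positive")
            if not (0 <= b.peak <= 1):
                raise ValueError("blob peak probability must be in [0, 1]")
        for a in self.artifact_bands:
            if not (0 <= a.col_start < a.col_end <= self.W):
                raise ValueError(f"artifact band columns out of bounds: {a}")
            if not (0 <= a.row_start < self.H and 0 < a.row_end <= self.H):
                raise ValueError(f"artifact band rows out of bounds: {a}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent probability map, exact masks, and true metric values."""

    probability_map: np.ndarray
    lipid_truth: BinaryMask
    artifact_truth: BinaryMask
    hidden_truth: BinaryMask
    lipid_fraction: float
    lcbi_total: float
    max_lcbi_2mm: float
    max_lcbi_4mm: float
    max_lcbi_2mm_blocked: float
    max_lcbi_4mm_blocked: float


def colormap_forward(p: np.ndarray | float) -> np.ndarray:
    """Map probabilities to the red-to-yellow scale: (255, round(255p), 0)."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rgb = np.empty(p.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = 255
    rgb[..., 1] = np.round(255 * p).astype(np.uint8)
    rgb[..., 2] = 0
    return rgb


def colormap_inverse(rgb: np.ndarray, tol: int = 0) -> np.ndarray:
    """Recover probabilities from red-to-yellow pixels; NaN off the scale.

    A pixel lies on the colour scale when red is within ``tol`` of 255 and
    blue within ``tol`` of 0; its probability is green/255.  Anything else
    (black artifacts, overlay colours) is marked invalid with NaN.  For real
    exports a generous ``tol`` gives an approximate inverse — display
    colormaps are not guaranteed to match this linear ramp exactly.
    """
    rgb = np.asarray(rgb)
    r = rgb[..., 0].astype(np.int16)
    g = rgb[..., 1].astype(np.float64)
    b = rgb[..., 2].astype(np.int16)
    on_scale = (np.abs(r - 255) <= tol) & (np.abs(b) <= tol)
    out = np.where(on_scale, g / 255.0, np.nan)
    return out


def _band_rows(band: ArtifactBand, H: int) -> np.ndarray:
    if band.row_start < band.row_end:
        return np.arange(band.row_start, band.row_end)
    return np.concatenate(
        [np.arange(band.row_start, H), np.arange(0, band.row_end)]
    )


def _probability_map(spec: SceneSpec) -> np.ndarray:
    rows = np.arange(spec.H, dtype=np.float64)[:, None]
    cols = np.arange(spec.W, dtype=np.float64)[None, :]
    p = np.zeros((spec.H, spec.W))
    for blob in spec.blobs:
        dr = np.abs(rows - blob.center_row)
        dr = np.minimum(dr, spec.H - dr)  # cyclic row distance
        d2 = (dr / blob.radius_rows) ** 2 + ((cols - blob.center_col) / blob.radius_cols) ** 2
        p += blob.peak * np.exp(-(d2**blob.sharpness))
    return np.clip(p, 0.0, 1.0)


def generate_chemogram(spec: SceneSpec) -> tuple[Chemogram, SyntheticTruth]:
    """Render a scene spec into a chemogram and its ground truth.

    Truth masks are computed on the noise-free latent map: lipid where the
    probability exceeds the LCP cut (0.6), artifact where a band is painted,
    hidden = artifact AND lipid.  The valid-pixel denominator for the true
    LCBI keeps hidden-lipid pixels (they are recoverable information) and
    drops the rest of the artifact area.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    p = _probability_map(spec)

    lipid = p > LCP_PROBABILITY_CUT
    artifact = np.zeros_like(lipid)
    for band in spec.artifact_bands:
        rr = _band_rows(band, spec.H)
        artifact[np.ix_(rr, np.arange(band.col_start, band.col_end))] = True
    hidden = artifact & lipid

    img = colormap_forward(p).astype(np.float64)
    for band in spec.artifact_bands:
        rr = _band_rows(band, spec.H)
        cc = np.arange(band.col_start, band.col_end)
        sub = np.full((rr.size, cc.size, 3), float(band.darkness))
        # weak residual lipid signal leaking through the shadow (green only)
        sub[:, :, 1] += spec.lipid_bleed * p[np.ix_(rr, cc)]
        img[np.ix_(rr, cc)] = sub
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    chem = Chemogram(pixels, spec.mm_per_column)

    lipid_m = BinaryMask(lipid, "lipid_combined")
    artifact_m = BinaryMask(artifact, "artifact")
    hidden_m = BinaryMask(hidden, "lipid_hidden")
    valid_m = _metrics.valid_mask_from(artifact_m, hidden_m, policy="reclaim")

    roi_cols = (0, spec.W)
    n_valid = int(valid_m.values.sum())
    frac = float((lipid & valid_m.values).sum() / n_valid) if n_valid else 0.0
    lcbi = _metrics.lcbi_total(lipid_m, valid_m, roi_cols) if n_valid else float("nan")

    def _max(window_mm: float, mode: str) -> float:
        if window_mm > spec.W * spec.mm_per_column:
            return float("nan")
        return _metrics.max_lcbi_window(
            lipid_m, valid_m, roi_cols, spec.mm_per_column, window_mm, mode=mode
        )[0]

    truth = SyntheticTruth(
        probability_map=p,
        lipid_truth=lipid_m,
        artifact_truth=artifact_m,
        hidden_truth=hidden_m,
        lipid_fraction=frac,
        lcbi_total=lcbi,
        max_lcbi_2mm=_max(2.0, "sliding"),
        max_lcbi_4mm=_max(4.0, "sliding"),
        max_lcbi_2mm_blocked=_max(2.0, "blocked"),
        max_lcbi_4mm_blocked=_max(4.0, "blocked"),
    )
    return chem, truth


def _band_lipid_fraction(blobs: list[LipidBlob], band: ArtifactBand, H: int) -> float:
    """Fraction of a band's pixels over lipid (probability > LCP cut)."""
    rr = _band_rows(band, H)[:, None].astype(np.float64)
    cc = np.arange(band.col_start, band.col_end, dtype=np.float64)[None, :]
    p = np.zeros((rr.size, cc.size))
    for blob in blobs:
        dr = np.abs(rr - blob.center_row)
        dr = np.minimum(dr, H - dr)
        d2 = (dr / blob.radius_rows) ** 2 + ((cc - blob.center_col) / blob.radius_cols) ** 2
        p += blob.peak * np.exp(-(d2**blob.sharpness))
    return float((np.clip(p, 0, 1) > LCP_PROBABILITY_CUT).mean())


def _visible_lipid_fraction(
    blobs: list[LipidBlob], bands: list[ArtifactBand], H: int, W: int
) -> float:
    """Fraction of the whole image that is lipid outside every band."""
    spec = object.__new__(SceneSpec)
    object.__setattr__(spec, "H", H)
    object.__setattr__(spec, "W", W)
    object.__setattr__(spec, "blobs", blobs)
    lipid = _probability_map(spec) > LCP_PROBABILITY_CUT
    for band in bands:
        lipid[np.ix_(_band_rows(band, H), np.arange(band.col_start, band.col_end))] = False
    return float(lipid.mean())


def random_scene(
    rng: np.random.Generator,
    H: int = 360,
    W: int = 200,
    mm_per_column: float = 0.25,
    noise_sd: float = 8.0,
) -> SceneSpec:
    """Draw a varied but contrast-rich scene from the study distribution.

    One to four lipid pools of mixed sizes, always a guide-wire band (15-30
    degrees tall, full pullback), and with probability 0.7 one calcification
    shadow placed over a lipid pool so the hidden-lipid path is exercised.
    """
    n_blobs = int(rng.integers(1, 5))
    blobs = [
        LipidBlob(
            center_row=float(rng.uniform(0, H)),
            center_col=float(rng.uniform(0.1 * W, 0.9 * W)),
            radius_rows=float(rng.uniform(0.07 * H, 0.15 * H)),
            radius_cols=float(rng.uniform(0.10 * W, 0.20 * W)),
            peak=float(rng.uniform(0.9, 1.0)),
        )
        for _ in range(n_blobs)
    ]
    deg_per_row = 360.0 / H
    gw_height = int(rng.integers(round(15 / deg_per_row), round(30 / deg_per_row) + 1))
    # The guide-wire shadow sits at a random rotation angle, but like the
    # calcification shadows it must be mostly background for mode-based
    # recovery to be meaningful: of ten angular draws, keep the one whose
    # lipid fraction is smallest (pools clustered at one angle can otherwise
    # bury the whole band in lipid).
    # One darkness level per scene: pixels lacking NIRS signal are rendered
    # at a console-fixed near-black level, so all shadows in an image share it.
    darkness = float(rng.uniform(5, 15))
    candidates = []
    for _ in range(10):
        gw_start = int(rng.integers(0, H))
        band = ArtifactBand(
            row_start=gw_start,
            row_end=(gw_start + gw_height) % H or H,
            col_start=0,
            col_end=W,
            darkness=darkness,
        )
        frac = _band_lipid_fraction(blobs, band, H)
        candidates.append((frac, band))
        if frac <= 0.05:
            break
    bands = [min(candidates, key=lambda t: t[0])[1]]
    if rng.random() < 0.7:
        # Calcification shadow partially covering one pool.  Mode-based
        # background estimation presumes the shadow region is mostly true
        # background, so the band extends well past the pool vertically and
        # placements whose lipid fraction exceeds 0.4 (e.g. a second pool
        # stacked under the same shadow) are redrawn (see methods note).
        for _ in range(10):
            target = blobs[int(rng.integers(0, n_blobs))]
            half_h = int(max(3, 2.5 * target.radius_rows))
            r0 = int(target.center_row - half_h) % H
            c0 = max(0, int(target.center_col - 0.6 * target.radius_cols))
            c1 = min(W, int(target.center_col + 0.1 * target.radius_cols))
            if c1 <= c0:
                continue
            band = ArtifactBand(
                row_start=r0,
                row_end=(r0 + 2 * half_h) % H or H,
                col_start=c0,
                col_end=c1,
                darkness=darkness,
            )
            if _band_lipid_fraction(blobs, band, H) <= 0.4:
                bands.append(band)
                break
        # Pools must stay PARTIALLY visible: if the shadows would leave less
        # than 1.5% of the image as visible lipid, the saturation stretch
        # has no lipid mass to anchor its upper tail and the scene is no
        # longer the contrast-rich regime being emulated; keep only the
        # guide-wire shadow then.
        if len(bands) == 2 and _visible_lipid_fraction(blobs, bands, H, W) < 0.015:
            bands = bands[:1]
    return SceneSpec(
        H=H,
        W=W,
        mm_per_column=mm_per_column,
        blobs=blobs,
        artifact_bands=bands,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_paired_dataset(
    n_cases: int,
    seed: int,
    H: int = 360,
    W: int = 200,
    mm_per_column: float = 0.25,
    noise_sd: float = 8.0,
) -> tuple[list[tuple[Chemogram, SyntheticTruth]], pd.DataFrame]:
    """Generate a seeded cohort of scenes plus a truth metric table.

    Returns the (chemogram, truth) pairs and a DataFrame with one row per
    case: true LCBI_total, maxLCBI_2mm and maxLCBI_4mm (sliding windows).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    rows = []
    for i in range(n_cases):
        spec = random_scene(rng, H=H, W=W, mm_per_column=mm_per_column,
                            noise_sd=noise_sd)
        chem, truth = generate_chemogram(spec)
        cases.append((chem, truth))
        rows.append(
            {
                "case_id": i,
                "lcbi_total": truth.lcbi_total,
                "max_lcbi_2mm": truth.max_lcbi_2mm,
                "max_lcbi_4mm": truth.max_lcbi_4mm,
            }
        )
    return cases, pd.DataFrame(rows)
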
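# Methods

## The measurement problem

Intravascular NIRS renders the chemical composition of a coronary artery as
a chemogram: columns are millimetres of automated pullback (0.5 mm/s
acquisition), rows are degrees of catheter rotation, and a red-to-yellow
scale encodes the per-location probability *p* of lipid core plaque.
Quantification reduces the map to the Lipid Core Burden Index
LCBI = 1000·(lipid pixels)/(valid pixels) over a physician-selected region
(typically the stented segment), plus windowed maxima (maxLCBI₂ₘₘ,
maxLCBI₄ₘₘ), block summaries and lipid arcs.

Two practical obstacles shape the pipeline. First, pixels without enough
optical signal are rendered black: a guide wire shadows a full-pullback
band of some 15–30°, and calcium shadows local patches — both can cover
lipid. Second, exported rasters carry no machine-readable calibration, so
mm-per-column is user-supplied configuration.

## Pipeline stages

**Coordinates.** Row 0 = 0°, column 0 = 0 mm; ROIs are half-open intervals
in mm mapped to the smallest covering column range. The rotation axis is
periodic: all connectivity (artifact regions, lipid pools) uses
8-connectivity plus wrap-around between the first and last rows, and lipid
arcs are longest *cyclic* runs of lipid rows in a column. A band painted
across the 0°/360° seam is therefore one region, never two.

**Contrast stretch.** Each RGB channel is treated as a grayscale image and
linearly rescaled so that 1% of the pixel mass saturates at each end
(quantiles by linear interpolation of order statistics; the exact quantile
method is configurable since conventions differ). A constant channel is
passed through unchanged — empty ROIs must not crash the pipeline. The
stretch is monotone and idempotent on already-stretched images.

**Artifact segmentation.** The red channel is saturated wherever the
colormap has data and near-zero in shadows, so its histogram is strongly
bimodal. The Otsu threshold — the 256-bin split maximizing between-class
variance — separates the two. Implementation detail that matters: candidate
splits are scored as exact integer fractions
(m₀W − w₀M)²/(w₀(W−w₀)), not floats, so near-ties are resolved
deterministically toward the smallest threshold. Pixels *at or below* the
threshold are artifact candidates (tie convention: the threshold bin is
dark). Components smaller than `min_artifact_area_px` (default 8 px) are
discarded as pixel noise; optional binary closing is off by default.

**Visible lipid.** Otsu on the green channel, computed over non-artifact
pixels only — including shadow pixels would inflate the dark class and bias
the threshold. Pixels strictly above the threshold and outside artifacts
are visible lipid.

**Hidden lipid.** Shadowed lipid retains a weak residual signal. Per
artifact region, independently: the background level is estimated as the
highest peak of the region's green-channel histogram, and pixels rising
more than `delta_threshold` (default 25 gray levels) above it are marked
lipid. Three numerical rules harden the peak estimate:

- the histogram is smoothed with a small triangular kernel (half-width 2)
  before taking the argmax — on noisy shadows the uint8 clip concentrates a
  spurious spike at gray 0 that can out-count the true background bin;
- ties still break toward the darker level (the safe assumption for
  shadows);
- if the peak lands in bin 0 anyway, the peak location is censored by the
  clip rather than estimated, and the region median (clip-invariant while
  background pixels are the majority) is used instead.

The analysed channel defaults to green (where lipid is most perceptible)
and is configurable. Hidden lipid is by construction a subset of the
artifact mask, and lowering `delta_threshold` can only add pixels.

**Combination and metrics.** The lipid mask is the union of visible and
hidden detections; hidden pixels bridging a shadow stripe merge the
flanking visible parts into one pool. The LCBI denominator ("valid"
pixels) is, by default, everything except artifact pixels *not* reclaimed
as hidden lipid — reclaimed pixels carry information; a strict variant
(exclude all artifact pixels) is always reported alongside. Windowed
maxima come in two modes: `blocked` tiles the ROI with consecutive
windows anchored at the ROI start (trailing partial tiles are skipped — a
shorter window is not a 2 mm segment), while `sliding` evaluates every
stride (default one column). Since blocked placements are a subset of
sliding placements, the sliding maximum dominates; lipid straddling a tile
boundary is the canonical case where a blocked console under-reads the
true windowed maximum. Ties in the argmax go to the smallest start. Block
chemogram values are 90th percentiles (linear interpolation) of per-block
probabilities recovered via the inverse colormap; the four colour classes
use the published cuts with overlapping boundaries (0.84, 0.98) assigned
to the lower class. Lipid arc per block is the maximum over the block's
columns of the longest cyclic lipid run — the per-column reading; an
angular-union variant would be strictly larger and is intentionally not
the default.

## Agreement statistics

`compare_methods` reproduces the standard method-comparison panel per
metric: two-sided paired Wilcoxon signed-rank (zero differences dropped;
exact sign-flip distribution via dynamic programming over doubled midranks
for ≤ 25 non-zero pairs, normal approximation with tie correction beyond),
ICC(2,1) — two-way random effects, absolute agreement, single measures,
the form appropriate for interchangeability since it penalises constant
offsets — with its 95% F-based interval (delegated to
`pingouin.intraclass_corr`; ICC(1,1) and ICC(3,1) selectable), and
Bland–Altman limits at mean ± 2 sample standard deviations of the
differences (factor 2.0, not 1.96, matching the convention of the
agreement plots this mirrors), plus medians with quartiles.

## The synthetic generator

Clinical chemograms are not distributable, so validation runs on generated
scenes with exact truth. A scene is: lipid pools as super-Gaussian bumps
p = peak·exp(−(d²)^k) with cyclic row distance; artifact bands (one
guide-wire band spanning the pullback, optional calcification shadows over
a pool); the linear red→yellow colormap (255, round(255p), 0), which is
exactly invertible to within 1/255; a residual green bleed under shadows;
additive clipped Gaussian noise. Truth masks are cut at *p* > 0.6 on the
noise-free latent map; hidden truth = artifact ∩ lipid; the true LCBI uses
the same reclaim-denominator convention as the pipeline.

Default conditions, chosen to emulate chemograms on which this style of
pipeline is workable, and what each means:

- **peak ∈ [0.9, 1.0], shoulder exponent k = 12** — pools read as
  near-binary patches, as they do on the display colormap. The exponent
  controls the width of the ambiguous ring between an intensity
  threshold's cut (~p 0.45–0.6) and the 0.6 truth cut; k = 12 keeps that
  ring a few percent of pool area. With soft Gaussian shoulders no
  threshold-based segmentation can match a fixed probability cut closely,
  which is a statement about such scenes rather than about the method.
- **noise σ = 8 gray levels** per channel, clipped to [0, 255]; the hidden
  threshold (25) sits ≈ 3σ above it.
- **shadow darkness ~U(5, 15)**, one value per scene — "no signal" pixels
  are rendered at a console-fixed black level, so all shadows in an image
  share it.
- **residual bleed 42 gray levels per unit p.** This is a deliberate
  modelling assumption: 42 = 25/0.6 places the delta-threshold crossing
  exactly at the 0.6 probability cut, the operating point at which
  background-plus-delta recovery can agree with probability-defined truth.
  Real shadows need not satisfy this alignment; with other bleed strengths
  the recovered contour corresponds to a different probability level.
- **scene admissibility.** Mode-based background estimation presumes a
  shadow region is mostly background, and thresholding presumes lipid is
  partially visible. The random-scene sampler enforces both from truth
  geometry alone: shadow placements whose lipid fraction would exceed 0.4
  are redrawn, and a calcification shadow that would leave under 1.5% of
  the image as visible lipid is dropped. Scenes violating these conditions
  are genuine failure modes of the method (see limitations), not useful
  test conditions.

What the generator does *not* emulate: the proprietary spectral prediction
model, speckle/motion artifacts, display anti-aliasing, or non-linear
display colormaps. Passing tests therefore demonstrate the segmentation
and metric machinery under the stated conditions; they are not evidence
about spectroscopy or about chemograms whose shadows are buried in lipid.

Validation scenes and cohorts run at 240×160 px (0.25 mm/column, 40 mm
pullback) with 20-scene recovery checks and 31-case agreement cohorts —
desk-scale sizes that keep the full suite fast while leaving every
per-pixel mechanism (seam wrap, shadows, windows) fully exercised. Under
these conditions the pipeline-vs-truth Jaccard of the combined lipid mask
averages ≈ 0.95 with occasional scenes near 0.86 (shadowed plateau pixels
sit only ~1.6–1.9σ above the detection cut, so a few percent of hidden
pixels are borderline), and per-case LCBI_total tracks truth within single
index points.

## Known limitations

- **Unimodality breaks Otsu.** On an image with no artifacts (or no
  lipid), Otsu still splits the noise and fabricates a class. Real
  chemograms essentially always contain a guide-wire shadow, and clinical
  use targets lipid-bearing segments, but fully featureless inputs are
  only handled in the exactly-constant case (degenerate-histogram flag).
- **Shadows buried in lipid are unrecoverable** by background-plus-delta
  analysis: if most of a region is lipid, the histogram peak *is* the
  lipid level. The generator excludes such scenes by design; on real data
  they would present as silent under-detection.
- **Inverse colormap is approximate on real exports.** The linear
  red→yellow ramp inverts exactly for generated images; console colormaps
  may deviate, so block probabilities recovered from real rasters carry an
  unquantified mapping error (`colormap_tolerance` controls how far off
  the ramp a pixel may sit before being treated as invalid).
- **Calibration is trusted, not verified**: a wrong mm-per-column scales
  all longitudinal quantities silently.
- **ICC confidence intervals** assume the usual two-way ANOVA normality;
  with near-perfect agreement the F statistics degenerate and the CI may
  be reported as NaN.
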
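# chemolipid

Automated lipid-core-plaque detection and Lipid Core Burden Index (LCBI)
metrics for intravascular near-infrared-spectroscopy (NIRS) chemograms.

A chemogram is a 2-D map of a coronary artery produced during a NIRS
catheter pullback: the x-axis is millimetres along the vessel, the y-axis is
degrees of catheter rotation, and a red-to-yellow colour scale encodes the
probability *p* that lipid core plaque (LCP) is present at each location.
Interventional-cardiology workflows summarize these maps with the LCBI —
the fraction of valid pixels with *p* > 0.6, scaled to 0–1000:

```
LCBI = 1000 · Area(lipid core plaque) / Area(selected region)
```

together with maxLCBI₂ₘₘ / maxLCBI₄ₘₘ (the maximal LCBI over any 2 mm /
4 mm longitudinal segment; maxLCBI₄ₘₘ ≥ 500 is a published high-risk
marker), per-2 mm block chemograms (block value = 90th percentile of the
block's pixel values, displayed in four colour classes: red *p* < 0.57,
orange 0.57 ≤ *p* ≤ 0.84, tan ≤ 0.98, yellow > 0.98), and the maximal lipid
arc per block.

This package is for researchers who have exported chemogram rasters and
want reproducible, scriptable lipid quantification offline. The pipeline:

1. **Preprocess** — split RGB channels, contrast-stretch each with 1%
   saturation at both intensity tails.
2. **Artifacts** — segment black shadow regions (guide wire, calcification)
   by Otsu thresholding of the adjusted red channel; connected components
   are tracked cyclically across the 0°/360° seam.
3. **Lipid** — Otsu on the non-artifact green pixels finds visible lipid;
   inside each artifact region, pixels rising more than an experimental
   threshold (default 25 gray levels) above the region's background
   (histogram peak) are recovered as lipid hidden under the shadow.
4. **Metrics** — LCBI_total, maxLCBI in blocked or sliding windows, block
   chemogram with colour classes, lipid arcs.
5. **Statistics** — paired Wilcoxon signed-rank (exact for ≤ 25 non-zero
   pairs), ICC(2,1) with 95% CI, Bland–Altman limits at mean ± 2·SD, for
   comparing two methods' per-case metric tables.

Because clinical chemograms come from proprietary consoles, the package
includes a synthetic chemogram generator with exact ground truth (latent
probability maps, artifact/lipid/hidden masks, true metric values) so every
stage is testable end to end.

## Worked example

Generate a synthetic case and analyse it:

```bash
chemolipid generate --n-cases 1 --seed 42 --out-dir scenes
chemolipid analyze --input scenes/case_000.png --mm-per-column 0.25 \
    --roi 5:45 --out-dir analysis
```

which prints

```
LCBI_total=58.4 maxLCBI_2mm=416.7@37.75mm maxLCBI_4mm=390.3@36.00mm
```

meaning: over the 5–45 mm region of interest, 5.84% of valid pixels are
lipid core plaque (LCBI_total 58.4 of 1000); the lipid-richest 2 mm segment
starts at 37.75 mm and has LCBI 416.7; the richest 4 mm segment starts at
36.0 mm with LCBI 390.3 — well under the 500 high-risk threshold, which the
tool reports but does not adjudicate. `analysis/report.json` carries the
full block chemogram (per-2 mm 90th-percentile values, colour classes,
lipid arcs in degrees), the strict-denominator LCBI variant, and a config
echo; `analysis/overlay.png` outlines the segmented pools on the input.

Compare two per-case metric tables (e.g. this pipeline vs another system):

```bash
chemolipid compare pipeline.csv reference.csv --out agreement.json
```

yielding, per metric, the Wilcoxon p, ICC(2,1) with CI, Bland–Altman
limits, and medians with quartiles.

The same functionality is available as a library:

```python
from chemolipid import CalibrationConfig, PipelineConfig, read_chemogram, run_pipeline

chem = read_chemogram("scenes/case_000.png", CalibrationConfig(mm_per_column=0.25))
result = run_pipeline(chem, PipelineConfig(mm_per_column=0.25))
print(result.report.lcbi_total)
```

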
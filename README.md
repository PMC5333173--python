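# volcoloc

Headless toolkit for analyzing multi-channel confocal z-stacks:

* **volume_io** — multi-page TIFF z-stack reading/writing (8/16-bit,
  channel-major or z-major page order), voxel-spacing metadata, intensity
  normalization, and the shared coordinate conventions (arrays indexed
  `(z, y, x)`; left-handed world frame in μm with x right, y up, z away from
  the viewer).
* **roi** — box, cylinder and freehand-polygon region-of-interest tools with
  per-axis scaling, rotation and translation, rasterized into a 2-D boolean
  footprint plus front/back z slice indices.
* **coloc** — threshold-based colocalization within an ROI: Manders' M1/M2,
  Manders' overlap coefficient, Pearson's correlation, percentage
  colocalization, the four colocalization visualization volumes
  (white-overlay / colocalized-only / colocalized-white / none), and the
  pseudo-colored intensity scatter histogram. The low threshold acts as a
  noise filter for all metrics; the high threshold bounds the percentage
  band and the visual masks.
* **render** — CPU direct volume rendering: perspective ray casting with
  front-to-back compositing and early termination, view-aligned slice
  compositing (works with the camera inside the volume), and
  pseudo-isosurface ray casting with gradient headlight shading.
* **synth** — synthetic Gaussian-blob phantoms with controllable channel
  overlap and amplitude correlation plus exact ground truth, and
  deterministic ramp pairs, so everything is testable without downloads.
* **trial_stats** — contingency-table statistics: 5→3 rating grouping,
  cell-wise Yates-corrected χ², χ² p-values, and Cramér's V
  `V = sqrt(χ² / (N·(k−1)))`.

## Tests

```sh
python -m pytest tests/
```

The suite includes oracle tests (naive triple-loop metric references,
exhaustive voxel-center ROI containment, back-to-front compositing),
property tests, and `tests/test_acceptance.py` with one test per acceptance
criterion.

## CLI

All subcommands live under a single entry point (also available as
`python -m volcoloc.cli`):

```sh
# generate a phantom with ground truth
volcoloc --seed 1 synth --spec phantom.json --out phantom.tif --truth truth.json

# rasterize an ROI shape (JSON) into a footprint PNG + z-range sidecar
volcoloc roi rasterize --shape roi.json --stack phantom.tif --out mask.png

# colocalization report (CSV) and pseudo-colored scatter plot
volcoloc coloc run --stack phantom.tif --ch-a 0 --ch-b 1 \
    --low 20,25 --high 255,255 --mode overlay_white \
    --out report.csv --scatter scatter.png

# render a frame
volcoloc render --stack phantom.tif --mode raycast --camera cam.json --out frame.png

# Yates chi-square, p-value and Cramér's V for a counts CSV
volcoloc stats chi2 --table table.csv --group
```

Global flags: `--verbose`, `--seed N`, `--log-json run.json` (writes a JSON
run log with inputs, parameters, version and seed).

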
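# octacnv

Quantitative morphometry of en-face OCTA neovascular lesions and the
accompanying two-group cohort statistics.

The package has four parts:

* **`octacnv.morphometry`** — converts a grayscale en-face angiogram plus a
  reader-supplied lesion mask into seven quantitative biomarkers: lesion
  size (mm²), vessel density, vessel length density, vessel diameter index
  (VD/VLD), vessel tortuosity (mean branch arc/chord ratio), box-counting
  fractal dimension and gliding-box lacunarity. Pixel size is corrected for
  ocular magnification from the eye's axial length (Bennett-style
  `(AL − 1.82)/(AL_ref − 1.82)` scaling), the lesion is binarized by Otsu's
  method over ROI pixels only, and the vessel mask is thinned to a 1-px
  skeleton that is decomposed into branches between junctions and endpoints.
* **`octacnv.cohort_stats`** — outcome grouping (≥ 15 ETDRS-letter gain at
  12 months), per-variable group comparison (uncorrected Pearson chi-square
  for categorical variables, Mann–Whitney U for continuous ones),
  univariable logistic regression with Wald 95% intervals, multivariable
  fitting of the variables passing a P < 0.1 univariable screen, linear
  regression of BCVA change on baseline SFCT, and the ellipsoid-zone
  subgroup comparison.
* **`octacnv.synthetic`** — deterministic generators for fractal fixtures
  with closed-form dimension, rasterized vessel networks with exact
  ground-truth pixel counts and per-branch arc/chord ratios, and two-group
  cohorts whose defaults match the published group summaries.
* **`octacnv.cli` / `octacnv.io` / `octacnv.config`** — file formats
  (TIFF/PNG images, CSV cohorts, JSON reports), YAML/JSON configuration and
  the `octacnv` command-line interface.

## CLI

```sh
# biomarkers for a batch of images (one ROI mask + one axial length per eye)
octacnv morphometry --images DIR --rois DIR --al-table al.csv \
    --config cfg.yaml --out OUTDIR

# cohort statistics from a per-eye CSV (column dictionary in octacnv/io.py)
octacnv cohort --cohort cohort.csv --config cfg.yaml --out OUTDIR

# synthetic inputs with ground truth
octacnv simulate --spec spec.yaml --out OUTDIR
```

Exit status: `0` all inputs processed, `1` partial failures (details in
`run_report.json`, always written), `2` configuration or schema error.

A simulate spec is a mapping with a `kind` key (`vessel_network`,
`fractal` or `cohort`), e.g.

```yaml
kind: vessel_network
seed: 4
n_branches: 5
wiggle_amplitude: 6.0
noise_sd: 8.0
```

## Notes on conventions

* Chi-square is Pearson's without continuity correction (this reproduces
  the published categorical p-values exactly).
* Binary-predictor odds ratios equal the cross-product ratio `ad/bc`; Wald
  standard errors equal `sqrt(1/a + 1/b + 1/c + 1/d)`.
* Fractal dimension and lacunarity default to the skeletonized image on a
  power-of-two box ladder from 2 px to ¼ of the ROI bounding box
  (`fd_substrate: binary` switches to the binarized lesion).
* Branch path length is measured on the pixel chain resampled every 6
  pixels, which removes the staircase-quantization bias of raw 8-connected
  step sums while leaving straight branches exact.
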
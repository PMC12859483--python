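# ploidymapper

Infer per-nucleus ploidy classes from segmented fluorescence-microscopy
images.

`ploidymapper` consumes object-level feature tables exported by a
segmentation tool (ilastik-dialect CSV: one row per segmented nucleus with
total marker intensity, size, variance of intensity, centroid and a user
label) together with the matching integer label images (TIFF/HDF5).  It
fits log2-scaled Gaussian mixtures to intensity/size features with an
in-repo EM implementation, selects the number of components by AIC/BIC,
names the components on a doubling ploidy ladder (`2C, 4C, 8C, …`,
optionally with a dropped `<2C/Unclassified` bottom class, an open-top
`≥` class, or a relative `2αC` ladder), quantifies classification
uncertainty from the posterior matrix, and renders spatial ploidy maps by
recoloring the label image.

## Modules

| module | role |
|---|---|
| `ploidymapper.feature_io` | CSV feature tables, TIFF/HDF5 label images, assignment output |
| `ploidymapper.preprocess` | label/threshold filters, reference (spermatid) QC + normalization, log2 transform |
| `ploidymapper.mixture` | EM Gaussian mixtures (spherical/diagonal/full/tied), AIC/BIC, model scan |
| `ploidymapper.ploidy_assign` | component→class ladder, classification, uncertainty intervals |
| `ploidymapper.summarize` | per-group proportions, class means + fold increases, two-sample Cramér–von Mises |
| `ploidymapper.ploidy_map` | label-image recoloring, max-rank 2D projection |
| `ploidymapper.synthetic` | doubling-cluster simulator (feature tables and label images with ground truth) |
| `ploidymapper.pipeline` / `cli` | config-driven end-to-end workflow, presets, run manifests |

## CLI

```bash
# full pipeline from a shipped preset (arabidopsis_2d, drosophila_2d,
# cardiomyocyte_2d) or from a YAML/JSON config
ploidymapper fit --preset drosophila_2d --input features.csv \
    --labels labels.tif --out run/ --seed 0
ploidymapper fit --config pipeline.yaml

# synthetic data with ground truth
ploidymapper simulate --out sim/ --seed 1 [--image]

# render a ploidy map from an existing assignment CSV
ploidymapper map --labels labels.tif --assignments run/assignments.csv --out map/

# reference-population QC gates only
ploidymapper qc --input features.csv --reference-label spermatid
```

`fit` writes `assignments.csv`, `model.json`, `summary.json`, the ploidy-map
images (when a label image is given), and `manifest.json`; re-running from a
manifest reproduces all outputs bit-identically.

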
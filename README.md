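# scatterhist

Predict stromal, epithelial and adipose tissue volume fractions from
wide-field light-scattering parameter maps, and validate the predictions
against quantitative analysis of digitized H&E histology slides.

The package implements, as a reusable and tested pipeline:

- **histology** — H&E slide quantitation: white balancing, optical-density
  color deconvolution onto a three-stain absorbance basis, HSV-saturation
  stain labeling (hematoxylin / eosin / no-stain), and voxelized (200 µm)
  epithelium / stroma / adipose volume-fraction maps with ROI statistics.
- **models** — the nine fraction-versus-property curves: two-parameter
  logistic fits for stroma and adipose and three-parameter Gaussian fits for
  epithelium against each of µs′ (reduced scattering), γ (phase-function
  parameter) and B (scatter power), via bounded multi-start nonlinear least
  squares, with rmse, adjusted R² and linearized 95% prediction intervals.
- **pipeline** — leave-one-out cross-validated fraction prediction (mean of
  the three per-property predictions, clipped to [0,1]), the
  epithelium:stroma ratio, threshold classification (fat if adipose > 0.5,
  malignant if ratio > 1, else benign), soft classification maps and
  photograph overlays.
- **metrics** — confusion matrices, one-vs-rest sensitivity / specificity /
  accuracy with exact Clopper–Pearson binomial confidence intervals, Pearson
  correlation, and two-sample t-tests (pooled by default, Welch optional).
- **synthetic** — generators with known ground truth: H&E-like slide
  rendering from region layouts, and a 31-specimen cohort (10 invasive /
  16 fibroglandular / 5 fat) in which a latent morphology axis drives both
  the tissue fractions and the optical properties.
- **io_cli** — file formats (PNG / float TIFF / CSV / JSON / YAML config),
  validation, logging, and the command-line interface.

## Command-line usage

```bash
# generate a synthetic cohort (CSV + per-specimen property-map TIFFs)
scatterhist simulate cohort --seed 7 --out work/sim

# segment an H&E slide into stain labels and fraction maps
scatterhist segment --slide slide.png --resolution 500 --out work/seg

# fit the nine models, then cross-validate
scatterhist fit --cohort work/sim/cohort.csv --out work/models.json
scatterhist loocv --cohort work/sim/cohort.csv --out work/predictions.csv

# render a soft classification map for one specimen
scatterhist classify-map --props work/sim/maps/S001_props.tif \
    --models work/models.json --out work/S001_softmap.png

# performance report with Clopper–Pearson CIs
scatterhist evaluate --predictions work/predictions.csv --out work/report.json

# everything end to end (simulates a cohort when none is given)
scatterhist run-all --seed 7 --out work/full
```

Exit codes: 0 success, 1 usage/config error, 2 data error, 3 computation
failure. All thresholds (fat 0.5, ratio 1.0, 200 µm voxels, 0.1 saturation
threshold, 95% CI level) live in one config object and can be overridden via
YAML (`--config`) or flags.

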
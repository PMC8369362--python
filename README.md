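# dbtdet

Single-phase lesion detection for digital breast tomosynthesis (DBT)
volumes, packaged with a synthetic phantom generator so the whole pipeline
— preprocessing, training, inference, and FROC evaluation — runs end to end
on CPU without any external data.

The pipeline:

1. **simulate** — seed-deterministic DBT-like phantoms (half-elliptical
   breast, bright skin rim, Gaussian-blob masses and spiculated
   architectural distortions), written as multi-frame DICOM plus
   `volume-index.csv` / `annotations.csv`.
2. **preprocess** — per-slice window leveling from the DICOM header, 2×2
   local-mean downscale, and breast masking (disk erosion of radius 5 +
   largest 8-connected component).
3. **train** — a compact fully convolutional dense-block detector (numpy,
   no framework needed) over 96×96-pixel grid cells; each cell predicts one
   confidence plus 4 box-regression values against a 256×256 anchor.
   Training samples positive slices (slice span = round(sqrt(mean box
   dimension))), crops around the ground-truth box, and optimizes with Adam
   (lr 0.001) under a configurable objectness loss (BCE, class-weighted
   BCE, focal, or reduced focal) plus MSE localization.  Early stopping
   monitors sensitivity at 2 FP/slice on fixed validation crops.
4. **predict** — full-volume inference: zero-padding to the grid,
   half-volume grid averaging, decoding, breast-region filtering (≥ half
   the box pixels inside the mask), and merge-based NMS (score ratio < 10
   and IoU > 0.5; merged score = max of the pair).
5. **evaluate** — volume- and breast-based FROC with the custom
   true-positive rule (center distance < max(half GT diagonal, 100 px) and
   predicted z within ±25% of volume slices around the GT center slice),
   plus patient-level percentile bootstrap CIs.

## CLI

```sh
dbt simulate   --preset small --counts 2,1,1,1 --seed 11 --out data/
dbt preprocess --index data/volume-index.csv --out prep/
dbt train      --config train.yaml --annotations data/annotations.csv \
               --index data/volume-index.csv --out run/
dbt predict    --checkpoint run/checkpoint.npz --index data/volume-index.csv \
               --out predictions.csv
dbt evaluate   --predictions predictions.csv --annotations data/annotations.csv \
               --index data/volume-index.csv --mode breast --fp 2 \
               --bootstrap 2000 --seed 7 --out report.json
```

`train.yaml` keys mirror `TrainConfig` / `LossConfig` / `DetectorConfig`,
e.g.:

```yaml
max_epochs: 30
patience: 25
batch_size: 2
crop: [192, 192]      # width, height; multiples of 96
loss:
  kind: focal         # bce | weighted_bce | focal | reduced_focal
  alpha: 0.25
  gamma: 2.0
detector:
  growth_rate: 4
  blocks: [1, 1]
```

Every run directory receives a `config.yaml` snapshot with the package
version and seed.

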
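# lymphodyn

End-to-end 4D lymphocyte motility analysis on multi-channel time-lapse
microscopy: cell tracking, translation/rotation-invariant movement
features, ellipse morphology, dense optical flow on the dendritic-network
channel, four "information level" phenotype classifiers with pixel-level
evaluation, layer-wise relevance propagation, and movement-based
directed/undirected clustering. A calibrated synthetic-movie generator
with full ground truth makes every stage testable without real
recordings.

## Layout

| module | contents |
| --- | --- |
| `lymphodyn.synthetic` | phenotype presets, scene rendering, pulsating-network channel, ground truth |
| `lymphodyn.io_preprocess` | `Movie` container, TIFF I/O, max-intensity projection, cut-off → blur → rescale |
| `lymphodyn.tracking` | blob detection, optimal-assignment linking (defaults 25/15/20/10/20/5000), gap imputation |
| `lymphodyn.features` | (v, a, r) invariant series, 15-entry summary vector, distances |
| `lymphodyn.morphology` | ellipse fits, per-track medians, morphology↔velocity PCA |
| `lymphodyn.stats` | group velocity summaries, Mann–Whitney U, displacement ∝ √t check |
| `lymphodyn.flow` | dense optical flow, 5 μm patch speeds, microenvironment correlation |
| `lymphodyn.classifiers` | levels 1–4 (logistic / 1D / 2D / 3D conv), intra/inter cross-validation |
| `lymphodyn.pixel_eval` | prediction maps, watershed fill, pixel AUC |
| `lymphodyn.interpret` | LRP relevance maps, coefficient report, prototypes |
| `lymphodyn.ddcluster` | feature selection + k-means directed/undirected clustering |
| `lymphodyn.nn` | numpy ND-conv network stack (training + LRP) used by the CNN levels |

## CLI

```bash
lymphodyn simulate   --config scene.yaml --out scene/
lymphodyn preprocess --in scene/ --out pre/ --pixel-size 0.4 --interval 20
lymphodyn track      --in pre/ --channel CD3 --out tracks.csv
lymphodyn features   --tracks tracks.csv --out features.csv
lymphodyn train      --features features.csv --task CD20-CD3 --scheme inter
lymphodyn ddcluster  --features features.csv --out dd.csv
```

`scene.yaml` holds `SceneConfig` fields, e.g.

```yaml
n_cells_per_phenotype: 5
n_frames: 40
frame_shape: [256, 256]
seed: 1
```

## Notes

- Speeds are reported in μm/min. `compute_velocity` defaults to the
  calibration-derived conversion (pixel_size · 60 / frame_interval); the
  conventional constant 1.23 is available as an explicit override
  (`lymphodyn.tracks.DEFAULT_CONVERSION_FACTOR`).
- Turning angles are signed, in [−π, π], clockwise positive in image
  coordinates (y down).
- CNN architectures default to the reference filter banks (128/64/32 for
  the 1D level, 256/128/64 for 2D/3D, kernel 3, pool 2, global max+avg
  pooling, L2 1e-3, dropout 0.25; SGD for the 1D level, Adam otherwise,
  lr 1e-3). `LevelSpec(filters=..., input_shape=...)` scales them down
  for desk-size experiments.
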
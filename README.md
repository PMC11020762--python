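# rectile

Rectangular-tile, locally adaptive random-forest land-cover classification
for multi-temporal raster imagery — with the full surrounding pipeline:
temporal compositing, vegetation-index and GLCM texture features,
error-matrix accuracy assessment, and a seeded synthetic-landscape
generator for testing everything without satellite downloads.

## The problem

Mapping land cover (here: grassland in an arid, highly heterogeneous
landscape) with a single classifier trained over a large extent assumes
the spectral signature of each class is the same everywhere.  Across a
climatic gradient it is not: the same cover type drifts through feature
space, and grassland in one region can look like bare soil in another.
`rectile` implements the *rectangular tile classification model*: the
extent is partitioned into equal rectangular tiles (default 3 × 5 = 15),
each tile gets its own random forest trained on the training samples of
the tile **and its 8 adjacent tiles**, and the per-tile predictions are
mosaicked into one map.  A 1 × 1 grid reduces exactly to the traditional
global model, which is also provided for comparison.

Accuracy is assessed with the standard error-matrix statistics: overall
accuracy OA = trace/N, Cohen's kappa = (p_o − p_e)/(1 − p_e), per-class
producer accuracy (PA, column-wise), user accuracy (UA, row-wise) and
F1 = 2·PA·UA/(PA+UA).

## Worked example

Simulate a drifted landscape, classify it both ways, and compare:

```sh
rectile simulate --out scene --seed 4 --rows 128 --cols 128 \
    --patch-scale 12 --drift 2.0 --n-per-class 100 --step-days 15
```

```
scene written to scene (13 dates, 600 samples)
```

Create `run.yaml`:

```yaml
scheme: EXP3        # optical spectral features, 12 bands
model: global
grid: {rows: 3, cols: 5}
classifier: {n_trees: 50, seed: 4}
paths:
  optical: scene/optical
  samples: scene/samples.csv
```

```sh
rectile run --config run.yaml --model global --out out
rectile run --config run.yaml --model tiled  --out out
rectile compare out/report_EXP3_global.json out/report_EXP3_tiled.json
```

The global run prints its accuracy report:

```
OA = 96.67%   kappa = 0.9600   n = 180
  cultivated  PA  96.67%  UA  96.67%  F1  96.67%
  woodland    PA  96.67%  UA 100.00%  F1  98.31%
  grassland   PA  93.33%  UA  93.33%  F1  93.33%
  waterbody   PA 100.00%  UA 100.00%  F1 100.00%
  building    PA 100.00%  UA 100.00%  F1 100.00%
  unused      PA  93.33%  UA  90.32%  F1  91.80%
```

the tiled run reaches `OA = 100.00%` on the same validation points, and
`compare` prints the deltas, tiled minus global:

```json
{
  "oa": 3.3333333333333286,
  "kappa": 0.040000000000000036,
  "f1": {
    "cultivated": 3.3333333333333286,
    "woodland": 1.6949152542372872,
    "grassland": 6.666666666666686,
    "waterbody": 0.0,
    "building": 0.0,
    "unused": 8.196721311475414
  }
}
```

The OA gain is the tile model absorbing the west–east drift: grassland
and bare-soil confusion concentrates where the drifted spectra collide,
and locally trained forests separate them again.  On a scene simulated
with `--drift 0` the two models agree to within a fraction of a point.

Everything is also available as a library:

```python
from rectile import (SceneSpec, generate_class_map, generate_scene,
                     generate_samples, ExperimentInputs, ExperimentConfig,
                     run_experiment)
```

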
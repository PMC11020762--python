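# Methods

`rectile` maps land cover on multi-temporal raster imagery with a random
forest, and its central design choice is *where* the forest is trained: once
for the whole study area (the global model) or once per rectangular tile of
the extent, with each tile's training set pooled from the tile and its
adjacent tiles (the tile model).  This note records the models,
parameters, numerical conventions and the design decisions that were
genuinely open.

## The tile classification model

The extent is partitioned into `n_rows x n_cols` equal rectangles (default
3 x 5 = 15, matching an extent wider east-west than north-south; row-major
ids from the top-left).  For tile *t* a forest is trained on the
training-split samples falling in `neighbors(t)` — queen contiguity: the
tile and its up-to-8 adjacent tiles — and applied only to the pixels of
*t*; tile predictions are mosaicked, so every valid pixel is predicted by
exactly one model.  Pooling neighbors rather than using the bare tile
trades locality against sample size and keeps tile boundaries from
becoming training-data cliffs.

Two conventions make the model well behaved:

* **Class fallback.** If a class has no pooled sample for some tile, its
  samples from the whole study area are borrowed, so every tile model can
  emit every class and per-tile maps remain comparable.  (The library
  function `pooled_training` does *not* fall back by default; the tiled
  classifier enables it.)
* **Seeding.** Tile *t* uses seed `base_seed + t`: runs are reproducible
  but tile forests are decorrelated.  With a 1 x 1 grid the tile model is
  bit-identical to the global model at the same seed — the pool is all
  samples and tile 0 gets the base seed; this reduction is tested.

The forest itself is scikit-learn's `RandomForestClassifier` with 50 trees
and sqrt(p) candidate features per split, hard labels only.  The base
learner sits behind a narrow train/predict contract (`train_model`) so it
could be substituted; only the random forest ships.

Rationale for the whole construction: a single global classifier assumes
the class-conditional feature distributions are stationary in space.  Over
a large heterogeneous extent — e.g. an aridity gradient several hundred km
wide — the same cover type drifts through spectral space, and a class in
one region can occupy the feature-space position of a different class in
another.  A locally trained forest sees locally unimodal classes.

## Pipeline

**Compositing.** Per-pixel temporal reduction (median / max / min / mean)
over a date window, over *valid* observations only; a composite pixel is
nodata iff it has zero valid observations in the window.  SAR stacks are
reduced to monthly medians over the growing season (May–October: six
composites); optical stacks to two period medians (growth and senescence).

**Window selection.** Class-mean vegetation-index curves from a
coarse-resolution stack, Savitzky–Golay smoothed (window 7, order 2,
mirrored edges — the filter is named in the source literature without
parameters; these are conventional for 8–10-day index series), drive the
compositing windows.  Two modes: `explicit` echoes hand-chosen dates (the
field practice is visual curve inspection; echoing keeps the dates in the
provenance record), `peak_fraction` is the reproducible stand-in: the
maximal contiguous span containing the argmax on which the curve stays at
or above `min + fraction * (max - min)` (default fraction 0.5, i.e.
full-width-at-half-maximum).  NDVI and MSAVI are composited by maximum;
NDWI and NDBI by minimum, their windows selected on the negated curve.

**Features.** Indices use the standard definitions — NDVI = (NIR−R)/(NIR+R),
NDWI = (G−NIR)/(G+NIR), NDBI = (SWIR1−NIR)/(SWIR1+NIR), MSAVI =
(2·NIR+1−√((2·NIR+1)²−8·(NIR−R)))/2 — with zero-denominator pixels nodata.
Textures are per-pixel GLCM statistics (ASM, CON, COR, ENT) on bands
quantized to equal-width gray levels between their valid min and max.
Defaults: 7 x 7 window, 32 levels, the four standard offsets
{(0,1),(1,0),(1,1),(1,−1)} pooled, symmetric counting, natural-log
entropy — common remote-sensing settings, since none are prescribed by the
source.  Degenerate-variance correlation is defined as 0 so texture
rasters are total functions.  Pairs involving nodata are excluded;
normalization is per-window over actually counted pairs, so edges and gaps
stay probability distributions.

**Feature schemes.** Seven nested combinations with fixed band counts:

| scheme | blocks | bands |
|---|---|---|
| EXP1 | SAR monthly VV | 6 |
| EXP2 | + SAR textures (4 x 6) | 30 |
| EXP3 | optical spectral (6 x 2 periods) | 12 |
| EXP4 | + index composites (4) | 16 |
| EXP5 | + optical textures (4 x 2 bands x 2 periods) | 32 |
| EXP6 | EXP2 + EXP4 | 46 |
| EXP7 | everything | 62 |

The optical texture source bands are red and NIR per period — the counts
(32 − 16 = 16 texture bands) constrain the choice to two bands x two
periods but not which bands; red/NIR carry the most vegetation contrast.
Index composites are computed once on their own windows (not per period),
which is what makes the index block 4 bands.

**Evaluation.** The error matrix is oriented rows = classification result,
columns = reference.  OA = 100·trace/N; kappa = (p_o − p_e)/(1 − p_e);
producer accuracy = diagonal over column sum; user accuracy = diagonal
over row sum; F1 = harmonic mean of PA and UA.  All metrics are computed
from exact integer counts and rounded only at display (2 d.p. for
percentages, 4 d.p. for kappa), so published tables can be reproduced
from their cells.  The train/validation split is seeded and stratified by
class at 70/30.

## The synthetic landscape generator

Real acquisitions for a study of this kind are hundreds of scenes; the
generator provides seeded stand-ins with the features the pipeline
actually exercises.

* **Class map**: one Gaussian random field per class, smoothed at
  `patch_scale` pixels, standardized, plus per-class offsets calibrated
  iteratively to a target class mix (default grassland-dominated with a
  large bare-soil fraction); label = argmax field.  Patch size grows with
  `patch_scale`; fractions land within a few points of the mix.
* **Optical stack** (6 canonical bands, 20 m pixels): per-class mean
  reflectances typical of cropland, woodland, semi-arid grassland, water,
  built-up and bare soil; Gaussian sensor noise (sd 0.02); per-date i.i.d.
  cloud gaps; values clipped to [0, 1].
* **Phenology**: a double-logistic greenness factor f(t) per vegetated
  class (green-up/senescence day-of-year, logistic rate 10 d, base 0.75,
  amplitude 0.5) enters each band as `f^w_b` with band weights
  w = (−0.3, −0.2, −0.6, +1.0, −0.3, −0.4): greening raises NIR and
  depresses visible/SWIR reflectance.  A factor common to all bands would
  cancel out of every normalized-difference index and leave the
  window-selection stage with flat curves; the band-weighted form is the
  minimal model in which index curves carry the seasonality they are
  meant to reveal.
* **SAR stack**: class-mean linear backscatter times multiplicative gamma
  speckle (5 looks, mean 1).
* **Coarse stack**: the optical stack block-averaged by a factor of 16
  (the ~20 m to ~500 m scale gap), used for index curves.
* **Spatial drift** (`drifted_model`): the stationarity violation the tile
  model exists for.  The per-band mean shift across the extent points
  along the grassland-to-bare-soil spectral difference and equals
  `strength` (default 2) such separations, so eastern grassland traverses
  the spectral space bare soil occupies further west.  The phenological
  signature drifts with it: green-up/senescence shift by 30 days across
  the extent and the seasonal amplitude fades eastward
  (`phenology_amplitude_drift = −1.6`), so the spectrally colliding
  grassland is also nearly aseasonal.  Without the phenological component
  the temporal signature is a drift-invariant separator and a global
  forest loses little; with it, the tile model wins consistently
  (measured: 10/10 seeds at 256 x 256, mean +2.8 OA points) while with
  zero drift the two models agree to well under a point.
* All randomness flows from one master seed through named `SeedSequence`
  substreams (class field / noise / clouds / speckle / sampling), so a
  scene is a pure function of its spec.

What the generator does **not** emulate: radiative transfer, topographic
illumination, mixed pixels at class boundaries beyond block averaging,
spatially correlated clouds, SAR geometry (layover/shadow), or
registration error.  Passing tests therefore demonstrate the pipeline's
correctness and the tile model's behavior under controlled spectral
drift — not sensor-level realism or accuracy attainable on real imagery.

## Numerical conventions and degenerate inputs

* Rasters: 0-based rows/cols; extent half-open `[x_min, x_max)` x
  `(y_min, y_max]`; points are pixel-center georeferenced; nodata is one
  mask shared across bands (any-band-invalid ⇒ pixel invalid).
* Tiles: half-open east/south edges, last row/column closed, so tiles
  partition the extent exactly; interior edge points belong to the tile
  right/below.
* Resampling covers the same extent at the target size, rounding dimension
  up; `average` pools input pixels by center containment and degrades to
  nearest when upsampling; default nearest for categorical data, average
  for continuous downsampling.
* Quantization maps the valid max to the top level; constant bands map to
  level 0.  `0 · ln 0 = 0` in entropy.  Constant curves are a hard error
  in peak-fraction window selection.  Single-class training sets degrade
  to constant predictors rather than erroring.
* Kappa returns NaN when chance agreement is exactly 1.

## Problem sizes

Default test and acceptance problem sizes were chosen as the smallest at
which the studied effects are stable: 256 x 256 scenes, 100 samples per
class and 10 seeds for the drift comparison; 128 x 128 for noise-free
recovery; 64 x 64 for the 14-scheme sweep (with a 5 x 5 GLCM window and 12
levels there, since texture cost dominates).

## Known limitations

* Tile grids are rectangular and equal-area only; tile-scale selection is
  not automated.
* Predictions are hard labels; no per-class probability rasters.
* No reprojection: all inputs must share one grid and CRS tag.
* The per-tile class-balancing floor/cap is available but has no
  principled default; the study conditions leave it off.
* GLCM cost grows with the number of distinct gray-level pairs; at 32
  levels on large rasters it is the slowest stage.
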
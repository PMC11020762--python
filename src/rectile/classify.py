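"""Random-forest classification: global model and rectangular-tile model.

The global model trains one forest on every training sample and applies it
everywhere.  The tile model trains one forest per tile on the samples pooled
from the tile and its 8 neighbors, predicts only that tile's pixels, and
mosaics the tiles into one map — a locally adaptive classifier that absorbs
within-class spectral drift across a large, heterogeneous extent.

A 1x1-tile run reduces exactly (bit-identically, at equal seed) to the
global model: the pool is every training sample and the tile covers the
whole extent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, RectileError
from .raster import (
    CLASSES,
    RasterStack,
    SamplePoint,
    sample_extract,
)
from .tiling import TileGrid, neighbors, tile_of_point

NODATA_LABEL = -1


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-forest configuration.

    ``n_trees`` defaults to 50; ``features_per_split`` is the number of
    candidate features per node split ('sqrt', 'all', or an int).
    """

    n_trees: int = 50
    features_per_split: str | int = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")

    @property
    def max_features(self):
        if self.features_per_split == "sqrt":
            return "sqrt"
        if self.features_per_split == "all":
            return None
        return int(self.features_per_split)


@dataclass
class LabelRaster:
    """Single-band integer class map with a legend.

    ``labels`` holds class ids (indices into ``legend``) or
    ``NODATA_LABEL`` (-1) for invalid pixels.
    """

    labels: np.ndarray
    transform: tuple[float, float, float, float]
    legend: tuple[str, ...] = CLASSES
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 2:
            raise ParameterError("labels must be a 2-D grid")
        top = int(self.labels.max(initial=NODATA_LABEL))
        if top >= len(self.legend):
            raise ParameterError("label value outside legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_name(self, value: int) -> str:
        return self.legend[value]

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        ox, oy, px, py = self.transform
        col = int(np.floor((x - ox) / px))
        row = int(np.floor((oy - y) / py))
        rows, cols = self.shape
        if not (0 <= row < rows and 0 <= col < cols):
            from .errors import ExtentError

            raise ExtentError(f"point ({x}, {y}) outside raster extent")
        return row, col


def write_label_raster(label: LabelRaster, path: str | Path) -> None:
    """Write a class map as an int16 GeoTIFF plus a JSON sidecar legend."""
    import tifffile

    ox, oy, px, py = label.transform
    tifffile.imwrite(
        str(path),
        label.labels.astype(np.int16),
        photometric="minisblack",
        description=json.dumps(
            {"legend": list(label.legend), "nodata": NODATA_LABEL,
             "crs_tag": label.crs_tag}
        ),
        extratags=[
            (33550, "d", 3, (float(px), float(py), 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
        ],
        metadata=None,
    )
    with open(str(path) + ".legend.json", "w") as fh:
        json.dump({i: n for i, n in enumerate(label.legend)}, fh, indent=2)


def read_label_raster(path: str | Path) -> LabelRaster:
    import tifffile

    from .errors import FormatError

    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            data = tf.asarray()
            scale = page.tags.get(33550)
            tiepoint = page.tags.get(33922)
            desc = page.tags.get("ImageDescription")
            scale_val = None if scale is None else tuple(scale.value)
            tp = None if tiepoint is None else tuple(tiepoint.value)
            desc_val = None if desc is None else desc.value
    except (tifffile.TiffFileError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if scale_val is None or tp is None:
        raise FormatError(f"{path} lacks GeoTIFF georeferencing tags")
    px, py = float(scale_val[0]), float(scale_val[1])
    ox, oy = float(tp[3]), float(tp[4])
    legend = CLASSES
    crs_tag = "unknown"
    if desc_val is not None:
        try:
            meta = json.loads(desc_val)
            legend = tuple(meta.get("legend", CLASSES))
            crs_tag = meta.get("crs_tag", crs_tag)
        except (json.JSONDecodeError, TypeError):
            pass
    return LabelRaster(np.asarray(data), (ox, oy, px, py), legend, crs_tag)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def train_model(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | Sequence[int],
    spec: ClassifierSpec = ClassifierSpec(),
    legend: tuple[str, ...] = CLASSES,
) -> RandomForestClassifier:
    """Fit a random forest on a feature table.

    ``labels`` may be class names (mapped through ``legend``) or integer
    ids.  Deterministic for a fixed seed.  A single-class training set is
    accepted (the forest degenerates to a constant predictor).
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ParameterError("empty training set")
    y = np.asarray(
        [legend.index(l) if isinstance(l, str) else int(l) for l in labels]
    )
    if len(y) != X.shape[0]:
        raise ParameterError("features and labels length mismatch")
    if not np.isfinite(X).all():
        raise ParameterError("training features contain missing values")
    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.max_features,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def _class_ordered(
    points: Sequence[SamplePoint], rows: Sequence[int]
) -> list[int]:
    """Row indices reordered by class (legend order), stable within class."""
    buckets: dict[str, list[int]] = {c: [] for c in CLASSES}
    for p, r in zip(points, rows):
        buckets[p.label].append(r)
    return [r for c in CLASSES for r in buckets[c]]


def _predict_pixels(
    model: RandomForestClassifier,
    stack: RasterStack,
    rows: np.ndarray,
    cols: np.ndarray,
    out: np.ndarray,
) -> None:
    if rows.size == 0:
        return
    X = stack.values[:, rows, cols].T.astype(np.float64)
    out[rows, cols] = model.predict(X).astype(np.int16)


def classify_global(
    feature_stack: RasterStack,
    samples: Sequence[SamplePoint],
    spec: ClassifierSpec = ClassifierSpec(),
) -> LabelRaster:
    """One forest trained on all training samples, applied to every valid pixel."""
    df = sample_extract(feature_stack, samples)
    feat_cols = feature_stack.band_names
    train_rows = [
        i
        for i, p in enumerate(samples)
        if p.split == "train" and bool(df["valid"].iloc[i])
    ]
    if not train_rows:
        raise RectileError("no valid training samples")
    order = _class_ordered([samples[i] for i in train_rows], train_rows)
    X = df.loc[order, feat_cols].to_numpy(dtype=np.float64)
    y = [samples[i].label for i in order]
    model = train_model(X, y, spec)
    out = np.full(feature_stack.shape, NODATA_LABEL, dtype=np.int16)
    rr, cc = np.nonzero(~feature_stack.nodata_mask)
    _predict_pixels(model, feature_stack, rr, cc, out)
    return LabelRaster(
        out, feature_stack.transform, CLASSES, feature_stack.crs_tag
    )


def _pixel_tiles(stack: RasterStack, grid: TileGrid) -> np.ndarray:
    """Tile id of every pixel center (vectorized tile_of_point)."""
    ox, oy, px, py = stack.transform
    rows, cols = stack.shape
    xs = ox + (np.arange(cols) + 0.5) * px
    ys = oy - (np.arange(rows) + 0.5) * py
    x_min, y_min, x_max, y_max = grid.extent
    c = np.clip(
        ((xs - x_min) / grid.tile_width).astype(int), 0, grid.n_cols - 1
    )
    r = np.clip(
        ((y_max - ys) / grid.tile_height).astype(int), 0, grid.n_rows - 1
    )
    return r[:, None] * grid.n_cols + c[None, :]


def classify_tiled(
    feature_stack: RasterStack,
    grid: TileGrid,
    samples: Sequence[SamplePoint],
    spec: ClassifierSpec = ClassifierSpec(),
    per_class_floor: int = 0,
    per_class_cap: int | None = None,
    progress: bool = False,
) -> LabelRaster:
    """Per-tile forests on neighbor-pooled samples, mosaicked into one map.

    Each tile t is classified by a forest trained on the training samples of
    t and its adjacent tiles (with a global per-class fallback so every tile
    model knows all classes), seeded at ``spec.seed + t`` so tile runs are
    reproducible yet decorrelated.  Every valid pixel is predicted by
    exactly one tile model.
    """
    df = sample_extract(feature_stack, samples)
    feat_cols = feature_stack.band_names
    # valid training points, keeping original row order
    vt_points: list[SamplePoint] = []
    vt_rows: list[int] = []
    for i, p in enumerate(samples):
        if p.split == "train" and bool(df["valid"].iloc[i]):
            vt_points.append(p)
            vt_rows.append(i)
    if not vt_points:
        raise RectileError("no valid training samples")
    point_tile = [tile_of_point(grid, p.x, p.y) for p in vt_points]
    train_all = set(range(len(vt_points)))
    by_tile: dict[int, list[int]] = {}
    for k, t in enumerate(point_tile):
        by_tile.setdefault(t, []).append(k)

    pix_tile = _pixel_tiles(feature_stack, grid)
    out = np.full(feature_stack.shape, NODATA_LABEL, dtype=np.int16)
    valid = ~feature_stack.nodata_mask
    import random as _random

    for t in range(grid.n_tiles):
        nb = neighbors(grid, t)
        pool = [k for nb_t in sorted(nb) for k in by_tile.get(nb_t, [])]
        # class bookkeeping with global fallback
        by_class: dict[str, list[int]] = {c: [] for c in CLASSES}
        for k in pool:
            by_class[vt_points[k].label].append(k)
        rng = _random.Random(spec.seed + t)
        chosen: list[int] = []
        for cls in CLASSES:
            members = sorted(by_class[cls])
            floor = max(per_class_floor, 1)
            if len(members) < floor:
                have = set(members)
                extra = [
                    k
                    for k in range(len(vt_points))
                    if vt_points[k].label == cls and k not in have
                ]
                if per_class_floor > 0:
                    members += extra[: floor - len(members)]
                elif not members:
                    members = extra
            if per_class_cap is not None and len(members) > per_class_cap:
                members = sorted(rng.sample(members, per_class_cap))
            chosen.extend(members)
        if not chosen:
            raise RectileError(
                f"tile {t}: empty training pool and no global fallback"
            )
        rows_df = [vt_rows[k] for k in chosen]
        X = df.loc[rows_df, feat_cols].to_numpy(dtype=np.float64)
        y = [vt_points[k].label for k in chosen]
        tile_spec = ClassifierSpec(
            spec.n_trees, spec.features_per_split, spec.seed + t
        )
        model = train_model(X, y, tile_spec)
        rr, cc = np.nonzero(valid & (pix_tile == t))
        _predict_pixels(model, feature_stack, rr, cc, out)
        if progress:
            print(f"tile {t + 1}/{grid.n_tiles}: {len(chosen)} samples, "
                  f"{rr.size} pixels")
    return LabelRaster(
        out, feature_stack.transform, CLASSES, feature_stack.crs_tag
    )
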
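"""Georeferenced raster data model and I/O.

A :class:`RasterStack` is a set of named, co-registered bands on one grid
with a shared nodata mask; a :class:`TemporalStack` is a date-ordered
sequence of such stacks from one sensor family.  Rasters are stored on disk
as GeoTIFF (tifffile with the ModelPixelScale / ModelTiepoint tags and a
JSON image description carrying band names, CRS tag and nodata policy).

Grid conventions: rows and columns are 0-based; the map extent is half-open,
``[x_min, x_max)`` in easting and ``(y_min, y_max]`` in northing with row 0
at the top; points are georeferenced to pixel centers.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ExtentError, FormatError, ParameterError, SchemaError

# Fixed land-cover scheme: six classes, in this canonical order.
CLASSES: tuple[str, ...] = (
    "cultivated",
    "woodland",
    "grassland",
    "waterbody",
    "building",
    "unused",
)
SPLITS: tuple[str, ...] = ("train", "validation")

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass
class RasterStack:
    """Named co-registered bands on one georeferenced grid.

    Parameters
    ----------
    band_names
        Ordered unique band identifiers.
    values
        Array of shape ``(bands, rows, cols)``.
    transform
        ``(origin_x, origin_y, pixel_size_x, pixel_size_y)`` with the origin
        at the top-left *corner* of pixel (0, 0) and both pixel sizes
        positive (rows increase southward).
    crs_tag
        Opaque coordinate-reference-system label; never interpreted.
    nodata_mask
        Boolean ``(rows, cols)`` array, ``True`` where the pixel is invalid
        in *any* band (single validity notion shared across bands).
    """

    band_names: list[str]
    values: np.ndarray
    transform: tuple[float, float, float, float]
    crs_tag: str = "local"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ParameterError("values must be (bands, rows, cols)")
        if self.values.shape[0] == 0:
            raise ParameterError("a RasterStack needs at least one band")
        if len(self.band_names) != self.values.shape[0]:
            raise ParameterError(
                f"{len(self.band_names)} band names for "
                f"{self.values.shape[0]} bands"
            )
        if len(set(self.band_names)) != len(self.band_names):
            raise ParameterError("band names must be unique")
        if self.transform[2] <= 0 or self.transform[3] <= 0:
            raise ParameterError("pixel sizes must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values).all(axis=0)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape[1:]:
                raise ParameterError("nodata mask shape mismatch")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(
                self.values
            ).all(axis=0)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the grid."""
        ox, oy, px, py = self.transform
        rows, cols = self.shape
        return (ox, oy - rows * py, ox + cols * px, oy)

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Pixel (row, col) containing map point (x, y); half-open cells."""
        ox, oy, px, py = self.transform
        col = int(np.floor((x - ox) / px))
        row = int(np.floor((oy - y) / py))
        rows, cols = self.shape
        if not (0 <= row < rows and 0 <= col < cols):
            raise ExtentError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        ox, oy, px, py = self.transform
        return ox + (col + 0.5) * px, oy - (row + 0.5) * py

    # -- bands ------------------------------------------------------------
    def band(self, name: str) -> np.ndarray:
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise SchemaError(
                f"band {name!r} not in {self.band_names}"
            ) from None
        return self.values[idx]

    def select(self, names: Sequence[str]) -> "RasterStack":
        idx = [self.band_names.index(n) for n in names]
        return RasterStack(
            list(names),
            self.values[idx],
            self.transform,
            self.crs_tag,
            self.nodata_mask.copy(),
        )

    def with_values(
        self, band_names: Sequence[str], values: np.ndarray,
        nodata_mask: np.ndarray | None = None,
    ) -> "RasterStack":
        """New stack on this grid with different payload."""
        return RasterStack(
            list(band_names),
            values,
            self.transform,
            self.crs_tag,
            self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
        )

    def masked(self) -> np.ndarray:
        """Values with nodata pixels set to NaN (copy)."""
        out = self.values.astype(np.float32, copy=True)
        out[:, self.nodata_mask] = np.nan
        return out


def concat_stacks(stacks: Iterable[RasterStack]) -> RasterStack:
    """Stack bands of several co-registered stacks into one.

    The shared nodata mask is the union of the inputs' masks.
    """
    stacks = list(stacks)
    if not stacks:
        raise ParameterError("nothing to concatenate")
    ref = stacks[0]
    names: list[str] = []
    mask = np.zeros(ref.shape, dtype=bool)
    for s in stacks:
        if s.shape != ref.shape or s.transform != ref.transform:
            raise ParameterError("stacks are not co-registered")
        names.extend(s.band_names)
        mask |= s.nodata_mask
    values = np.concatenate([s.values for s in stacks], axis=0)
    return RasterStack(names, values, ref.transform, ref.crs_tag, mask)


@dataclass
class TemporalStack:
    """Date-ordered sequence of co-registered RasterStacks."""

    entries: list[tuple[_dt.date, RasterStack]]
    sensor_tag: Literal["sar", "optical", "coarse"] = "optical"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ParameterError("a TemporalStack needs at least one entry")
        dates = [d for d, _ in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ParameterError("dates must be strictly increasing")
        ref = self.entries[0][1]
        for _, s in self.entries:
            if s.shape != ref.shape or s.transform != ref.transform:
                raise ParameterError("entries are not co-registered")

    @property
    def dates(self) -> list[_dt.date]:
        return [d for d, _ in self.entries]

    def between(self, start: _dt.date, end: _dt.date) -> "list[tuple[_dt.date, RasterStack]]":
        return [(d, s) for d, s in self.entries if start <= d <= end]


@dataclass(frozen=True)
class SamplePoint:
    """Georeferenced labelled point with a train/validation tag."""

    x: float
    y: float
    label: str
    split: str = "train"

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ParameterError(f"unknown class {self.label!r}")
        if self.split not in SPLITS:
            raise ParameterError(f"unknown split {self.split!r}")


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(stack: RasterStack, path: str | Path) -> None:
    """Write a stack as a float32 GeoTIFF (nodata pixels stored as NaN)."""
    ox, oy, px, py = stack.transform
    description = json.dumps(
        {
            "band_names": stack.band_names,
            "crs_tag": stack.crs_tag,
            "nodata": "nan",
        }
    )
    data = stack.masked()
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(px), float(py), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
    ]
    kwargs = {}
    if data.shape[0] == 1:
        data = data[0]  # single band: plain grayscale page
    else:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=description,
        extratags=extratags,
        metadata=None,
        **kwargs,
    )


def read_raster(path: str | Path) -> RasterStack:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            data = tf.asarray()
            tags = page.tags
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
            desc_tag = tags.get("ImageDescription")
            scale_val = None if scale is None else tuple(scale.value)
            tp = None if tiepoint is None else tuple(tiepoint.value)
            desc_val = None if desc_tag is None else desc_tag.value
    except (tifffile.TiffFileError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read {path} as GeoTIFF: {exc}") from exc
    if scale_val is None or tp is None:
        raise FormatError(f"{path} lacks GeoTIFF georeferencing tags")
    px, py = float(scale_val[0]), float(scale_val[1])
    # origin of the raster = map coords of raster point (i, j) shifted back
    ox = float(tp[3]) - float(tp[0]) * px
    oy = float(tp[4]) + float(tp[1]) * py
    band_names = None
    crs_tag = "unknown"
    if desc_val is not None:
        try:
            meta = json.loads(desc_val)
            band_names = meta.get("band_names")
            crs_tag = meta.get("crs_tag", crs_tag)
        except (json.JSONDecodeError, TypeError):
            pass
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if band_names is None:
        band_names = [f"band_{i + 1}" for i in range(data.shape[0])]
    return RasterStack(
        list(band_names), data, (ox, oy, px, py), crs_tag
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(
    stack: RasterStack,
    target_pixel_size: float,
    method: Literal["nearest", "bilinear", "average"] = "nearest",
) -> RasterStack:
    """Regrid a stack to a new square pixel size over the same extent.

    Output dimensions round up so the target grid covers the full extent.
    ``average`` pools every input pixel whose center falls in an output
    cell (block mean); when the target is finer than the native grid it
    degrades to ``nearest``.  Nodata propagates: an output pixel is nodata
    iff it receives no valid input.
    """
    if target_pixel_size <= 0:
        raise ParameterError("target pixel size must be positive")
    ox, oy, px, py = stack.transform
    rows, cols = stack.shape
    out_cols = int(np.ceil(cols * px / target_pixel_size))
    out_rows = int(np.ceil(rows * py / target_pixel_size))
    t = float(target_pixel_size)
    new_transform = (ox, oy, t, t)
    vals = stack.masked()

    if method == "average" and t >= min(px, py):
        sums = np.zeros((stack.n_bands, out_rows, out_cols))
        cnts = np.zeros((out_rows, out_cols))
        rr, cc = np.nonzero(~stack.nodata_mask)
        # map input pixel centers into output cells
        xs = ox + (cc + 0.5) * px
        ys = oy - (rr + 0.5) * py
        oc = np.clip(((xs - ox) / t).astype(int), 0, out_cols - 1)
        orow = np.clip(((oy - ys) / t).astype(int), 0, out_rows - 1)
        np.add.at(cnts, (orow, oc), 1.0)
        for b in range(stack.n_bands):
            np.add.at(sums[b], (orow, oc), stack.values[b, rr, cc])
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sums / cnts
        mask = cnts == 0
        out[:, mask] = np.nan
        return RasterStack(
            stack.band_names, out, new_transform, stack.crs_tag, mask
        )

    # pixel-center lookup coordinates in input index space
    oc = np.arange(out_cols)
    orow = np.arange(out_rows)
    xs = (oc + 0.5) * t / px - 0.5
    ys = (orow + 0.5) * t / py - 0.5
    cgrid, rgrid = np.meshgrid(xs, ys)
    if method in ("nearest", "average"):
        ri = np.clip(np.round(rgrid).astype(int), 0, rows - 1)
        ci = np.clip(np.round(cgrid).astype(int), 0, cols - 1)
        out = vals[:, ri, ci]
    elif method == "bilinear":
        from scipy.ndimage import map_coordinates

        out = np.stack(
            [
                map_coordinates(
                    vals[b], [rgrid, cgrid], order=1, mode="nearest",
                    cval=np.nan,
                )
                for b in range(stack.n_bands)
            ]
        )
    else:
        raise ParameterError(f"unknown resampling method {method!r}")
    mask = ~np.isfinite(out).all(axis=0)
    out = np.where(np.isfinite(out), out, np.nan)
    return RasterStack(
        stack.band_names, out, new_transform, stack.crs_tag, mask
    )


# ---------------------------------------------------------------------------
# Point extraction and sample I/O
# ---------------------------------------------------------------------------

def sample_extract(
    stack: RasterStack,
    points: Sequence[SamplePoint],
    on_outside: Literal["flag", "error"] = "flag",
) -> pd.DataFrame:
    """Pixel values of the cell containing each point.

    Returns a DataFrame with one row per point (input order preserved),
    the stack's bands as columns, plus ``label``, ``split`` and ``valid``.
    ``valid`` is False for points outside the extent or on nodata pixels.
    """
    n = len(points)
    out = np.full((n, stack.n_bands), np.nan, dtype=np.float64)
    valid = np.zeros(n, dtype=bool)
    for i, p in enumerate(points):
        try:
            r, c = stack.rowcol(p.x, p.y)
        except ExtentError:
            if on_outside == "error":
                raise
            continue
        if stack.nodata_mask[r, c]:
            continue
        out[i] = stack.values[:, r, c]
        valid[i] = True
    df = pd.DataFrame(out, columns=stack.band_names)
    df["label"] = [p.label for p in points]
    df["split"] = [p.split for p in points]
    df["valid"] = valid
    return df


def write_temporal_stack(tstack: TemporalStack, directory: str | Path) -> None:
    """Write a temporal stack as a directory of date-named GeoTIFFs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for date, stack in tstack.entries:
        write_raster(stack, directory / f"{date.isoformat()}.tif")


def read_temporal_stack(
    directory: str | Path, sensor_tag: str = "optical"
) -> TemporalStack:
    """Read a temporal stack from a directory of ``YYYY-MM-DD.tif`` files."""
    directory = Path(directory)
    entries = []
    for f in sorted(directory.glob("*.tif")):
        try:
            date = _dt.date.fromisoformat(f.stem)
        except ValueError as exc:
            raise FormatError(
                f"{f.name}: temporal stack files must be named YYYY-MM-DD.tif"
            ) from exc
        entries.append((date, read_raster(f)))
    if not entries:
        raise FormatError(f"no .tif files in {directory}")
    return TemporalStack(entries, sensor_tag)


def read_samples_csv(path: str | Path) -> list[SamplePoint]:
    df = pd.read_csv(path)
    missing = {"x", "y", "label", "split"} - set(df.columns)
    if missing:
        raise SchemaError(f"sample CSV missing columns: {sorted(missing)}")
    return [
        SamplePoint(float(r.x), float(r.y), str(r.label), str(r.split))
        for r in df.itertuples()
    ]


def write_samples_csv(points: Sequence[SamplePoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "x": [p.x for p in points],
            "y": [p.y for p in points],
            "label": [p.label for p in points],
            "split": [p.split for p in points],
        }
    ).to_csv(path, index=False)


def read_samples_geojson(path: str | Path) -> list[SamplePoint]:
    with open(path) as fh:
        try:
            gj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path} is not valid GeoJSON") from exc
    feats = gj.get("features", [])
    points = []
    for f in feats:
        geom = f.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError("sample GeoJSON must contain Point features")
        x, y = geom["coordinates"][:2]
        props = f.get("properties") or {}
        points.append(
            SamplePoint(
                float(x), float(y),
                str(props.get("label")),
                str(props.get("split", "train")),
            )
        )
    return points


def write_samples_geojson(
    points: Sequence[SamplePoint], path: str | Path
) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                "properties": {"label": p.label, "split": p.split},
            }
            for p in points
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)
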
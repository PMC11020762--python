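"""Temporal compositing and compositing-window selection.

SAR stacks are reduced to monthly median composites over the growing
season; optical stacks are reduced over date windows chosen from smoothed
coarse-resolution vegetation-index curves (the seasonal index trajectory of
the target class picks the window).  Reducers operate per pixel over the
valid observations only, so cloud/speckle gaps at individual dates do not
punch holes in the composite as long as one valid observation exists.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateCurveError, ExtentError, ParameterError
from .raster import RasterStack, SamplePoint, TemporalStack

Reducer = Literal["median", "max", "min", "mean"]
_REDUCERS = {
    "median": np.nanmedian,
    "max": np.nanmax,
    "min": np.nanmin,
    "mean": np.nanmean,
}


@dataclass(frozen=True)
class TimeWindow:
    """Inclusive date window [start, end]."""

    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError("window start after end")

    @staticmethod
    def parse(start: str, end: str) -> "TimeWindow":
        return TimeWindow(
            _dt.date.fromisoformat(start), _dt.date.fromisoformat(end)
        )


@dataclass
class IndexCurve:
    """Class-mean vegetation-index time series."""

    dates: list[_dt.date]
    values: np.ndarray
    index_name: str = "NDVI"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ParameterError("dates and values must have equal length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ParameterError("curve dates must be increasing")


def temporal_composite(
    tstack: TemporalStack, window: TimeWindow, reducer: Reducer = "median"
) -> RasterStack:
    """Per-pixel reduction of all stack entries inside a date window.

    A pixel is nodata in the composite iff it has zero valid observations
    within the window.
    """
    if reducer not in _REDUCERS:
        raise ParameterError(f"unknown reducer {reducer!r}")
    entries = tstack.between(window.start, window.end)
    if not entries:
        raise ExtentError(
            f"no entries in {window.start}..{window.end}; available dates: "
            + ", ".join(str(d) for d in tstack.dates)
        )
    ref = entries[0][1]
    cube = np.stack([s.masked() for _, s in entries])  # (t, b, r, c)
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        out = _REDUCERS[reducer](cube, axis=0)
    mask = ~np.isfinite(out).all(axis=0)
    out = np.where(np.isfinite(out), out, np.nan)
    return RasterStack(
        list(ref.band_names), out, ref.transform, ref.crs_tag, mask
    )


def monthly_composites(
    tstack: TemporalStack,
    months: Sequence[tuple[int, int]],
    reducer: Reducer = "median",
) -> list[RasterStack]:
    """One composite per calendar (year, month), ordered by calendar.

    Band names get a ``_YYYY-MM`` suffix so monthly composites can be
    concatenated into a single feature stack.
    """
    out = []
    for year, month in sorted(set(months)):
        last = calendar.monthrange(year, month)[1]
        window = TimeWindow(_dt.date(year, month, 1), _dt.date(year, month, last))
        comp = temporal_composite(tstack, window, reducer)
        suffix = f"{year:04d}-{month:02d}"
        comp.band_names = [f"{n}_{suffix}" for n in comp.band_names]
        out.append(comp)
    return out


def sg_smooth(
    curve: IndexCurve, window_length: int = 7, poly_order: int = 2
) -> IndexCurve:
    """Savitzky–Golay smoothing of an index curve (mirrored edges).

    The filter fits a local polynomial of ``poly_order`` in a sliding
    window, which preserves phenological peak timing better than a moving
    average while suppressing impulsive noise (residual clouds, snow).
    """
    if window_length % 2 != 1:
        raise ParameterError("window_length must be odd")
    if poly_order >= window_length:
        raise ParameterError("poly_order must be < window_length")
    if len(curve.values) < window_length:
        raise ParameterError("curve shorter than the smoothing window")
    smoothed = savgol_filter(
        curve.values, window_length, poly_order, mode="mirror"
    )
    return IndexCurve(list(curve.dates), smoothed, curve.index_name)


def mean_index_curve(
    coarse: TemporalStack,
    index_name: str,
    class_points: Sequence[SamplePoint],
) -> IndexCurve:
    """Class-mean index trajectory over a coarse-resolution stack.

    For each date, computes the index (see :func:`rectile.features.compute_index`)
    and averages it over the valid pixels containing the given points.
    Dates where every point falls on nodata get NaN.
    """
    from .features import compute_index

    if not class_points:
        raise ParameterError("need at least one class point")
    dates, means = [], []
    for date, stack in coarse.entries:
        idx = compute_index(stack, index_name)
        vals = []
        for p in class_points:
            try:
                r, c = idx.rowcol(p.x, p.y)
            except ExtentError:
                continue
            if not idx.nodata_mask[r, c]:
                vals.append(idx.values[0, r, c])
        dates.append(date)
        means.append(float(np.mean(vals)) if vals else np.nan)
    return IndexCurve(dates, np.asarray(means), index_name)


def select_window(
    curve: IndexCurve,
    mode: Literal["peak_fraction", "explicit"] = "peak_fraction",
    fraction: float = 0.5,
    explicit: TimeWindow | None = None,
) -> TimeWindow:
    """Choose a compositing window from an index curve.

    ``explicit`` mode echoes a hand-chosen window (visual curve inspection
    is the field practice; this keeps it in the provenance record).
    ``peak_fraction`` mode is the reproducible rule: the maximal contiguous
    date span, containing the curve's argmax, on which the value stays at or
    above ``min + fraction * (max - min)``.  For indices whose informative
    composite is a minimum (water / built-up indices), apply this to the
    negated curve.
    """
    if mode == "explicit":
        if explicit is None:
            raise ParameterError("explicit mode needs a window")
        return explicit
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    vals = np.asarray(curve.values, dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise DegenerateCurveError("curve has no finite values")
    vmin = np.nanmin(vals)
    vmax = np.nanmax(vals)
    if vmax == vmin:
        raise DegenerateCurveError(
            "constant curve: peak-fraction window is undefined"
        )
    threshold = vmin + fraction * (vmax - vmin)
    above = finite & (vals >= threshold)
    peak = int(np.nanargmax(vals))
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(vals) - 1 and above[hi + 1]:
        hi += 1
    return TimeWindow(curve.dates[lo], curve.dates[hi])


def negate(curve: IndexCurve) -> IndexCurve:
    """Sign-flipped curve (for minimum-composite window selection)."""
    return IndexCurve(list(curve.dates), -curve.values, curve.index_name)
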
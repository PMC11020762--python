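"""End-to-end experiment runner: composites -> features -> classify -> evaluate.

An *experiment* is one (feature scheme, classification model) pair: schemes
EXP1..EXP7 select increasingly rich feature blocks (Table-style nested
design), the model is either ``global`` or ``tiled``.  The runner reduces
the input temporal stacks into composites, assembles the scheme's feature
stack, trains and applies the classifier, and scores the resulting map
against the validation points.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import __version__
from .classify import ClassifierSpec, LabelRaster, classify_global, classify_tiled
from .compositing import (
    IndexCurve,
    TimeWindow,
    mean_index_curve,
    monthly_composites,
    negate,
    select_window,
    sg_smooth,
    temporal_composite,
)
from .errors import ParameterError
from .evaluate import AccuracyReport, ErrorMatrix, accuracy_report, confusion
from .features import (
    INDEX_NAMES,
    CompositeSet,
    FeatureScheme,
    GlcmParams,
    assemble_features,
    compute_index,
)
from .raster import SamplePoint, TemporalStack
from .tiling import make_grid

#: indices composited by their maximum (greenness peaks) vs minimum
INDEX_REDUCER = {"NDVI": "max", "MSAVI": "max", "NDWI": "min", "NDBI": "min"}


@dataclass
class ExperimentInputs:
    """In-memory inputs of one experiment."""

    optical: TemporalStack | None = None
    sar: TemporalStack | None = None
    coarse: TemporalStack | None = None
    samples: list[SamplePoint] = field(default_factory=list)


@dataclass
class ExperimentConfig:
    """Everything that determines an experiment's output besides the inputs."""

    scheme: str = "EXP7"
    model: Literal["global", "tiled"] = "tiled"
    grid_rows: int = 3
    grid_cols: int = 5
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    #: explicit compositing windows keyed by 'growth', 'senescence' and
    #: index names; ignored when window_mode == 'peak_fraction'
    windows: dict[str, TimeWindow] = field(default_factory=dict)
    window_mode: Literal["explicit", "peak_fraction"] = "explicit"
    peak_fraction: float = 0.5
    sg_window: int = 7
    sg_order: int = 2
    glcm: GlcmParams = field(default_factory=GlcmParams)
    per_class_floor: int = 0
    per_class_cap: int | None = None

    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "model": self.model,
            "grid": [self.grid_rows, self.grid_cols],
            "classifier": {
                "n_trees": self.classifier.n_trees,
                "features_per_split": self.classifier.features_per_split,
                "seed": self.classifier.seed,
            },
            "windows": {
                k: [str(w.start), str(w.end)] for k, w in self.windows.items()
            },
            "window_mode": self.window_mode,
            "peak_fraction": self.peak_fraction,
            "sg": [self.sg_window, self.sg_order],
            "glcm": {
                "window_radius": self.glcm.window_radius,
                "levels": self.glcm.levels,
                "offsets": list(map(list, self.glcm.offsets)),
                "symmetric": self.glcm.symmetric,
            },
            "per_class_floor": self.per_class_floor,
            "per_class_cap": self.per_class_cap,
        }
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ExperimentResult:
    report: AccuracyReport
    label: LabelRaster
    matrix: ErrorMatrix
    provenance: dict

    @property
    def oa(self) -> float:
        return self.report.oa


def _full_window(tstack: TemporalStack) -> TimeWindow:
    return TimeWindow(tstack.dates[0], tstack.dates[-1])


def index_stack(optical: TemporalStack, index_name: str) -> TemporalStack:
    """Per-date vegetation-index stack derived from an optical stack."""
    return TemporalStack(
        [(d, compute_index(s, index_name)) for d, s in optical.entries],
        optical.sensor_tag,
    )


def derive_windows(
    inputs: ExperimentInputs, cfg: ExperimentConfig
) -> dict[str, TimeWindow]:
    """Compositing windows, explicit or derived from coarse index curves.

    In ``peak_fraction`` mode the grassland training points and the coarse
    stack drive the choice: each index's smoothed class-mean curve (negated
    for the minimum-composited NDWI/NDBI) yields its own window, and the
    optical growth/senescence periods split the full optical range at the
    NDVI peak date.
    """
    if cfg.window_mode == "explicit":
        windows = dict(cfg.windows)
        base = inputs.optical or inputs.sar
        for key in ("growth", "senescence", *INDEX_NAMES):
            if key not in windows and base is not None:
                windows[key] = _full_window(base)
        return windows
    if inputs.coarse is None:
        raise ParameterError("peak_fraction windows need a coarse stack")
    grass = [
        p for p in inputs.samples
        if p.label == "grassland" and p.split == "train"
    ]
    if not grass:
        raise ParameterError("peak_fraction windows need grassland samples")
    windows: dict[str, TimeWindow] = {}
    ndvi_curve: IndexCurve | None = None
    for name in INDEX_NAMES:
        curve = sg_smooth(
            mean_index_curve(inputs.coarse, name, grass),
            cfg.sg_window, cfg.sg_order,
        )
        sel = curve if INDEX_REDUCER[name] == "max" else negate(curve)
        windows[name] = select_window(sel, "peak_fraction", cfg.peak_fraction)
        if name == "NDVI":
            ndvi_curve = curve
    peak = ndvi_curve.dates[int(np.nanargmax(ndvi_curve.values))]
    full = _full_window(inputs.optical) if inputs.optical else _full_window(inputs.coarse)
    windows["growth"] = TimeWindow(full.start, peak)
    windows["senescence"] = TimeWindow(peak + _dt.timedelta(days=1), full.end)
    return windows


def build_composites(
    inputs: ExperimentInputs, cfg: ExperimentConfig
) -> CompositeSet:
    """Reduce the temporal stacks into the composites the scheme consumes."""
    scheme = FeatureScheme.by_name(cfg.scheme)
    windows = derive_windows(inputs, cfg)
    out = CompositeSet()
    need = set(scheme.blocks)
    if need & {"s1_pol", "s1_tex"}:
        if inputs.sar is None:
            raise ParameterError(f"scheme {cfg.scheme} needs a SAR stack")
        months = sorted({(d.year, d.month) for d in inputs.sar.dates})
        out.s1_monthly = monthly_composites(inputs.sar, months, "median")
    if need & {"s2_spec", "s2_tex", "s2_vi"}:
        if inputs.optical is None:
            raise ParameterError(f"scheme {cfg.scheme} needs an optical stack")
    if need & {"s2_spec", "s2_tex"}:
        out.s2_periods = [
            temporal_composite(inputs.optical, windows["growth"], "median"),
            temporal_composite(inputs.optical, windows["senescence"], "median"),
        ]
    if "s2_vi" in need:
        out.s2_indices = []
        for name in INDEX_NAMES:
            reducer = INDEX_REDUCER[name]
            comp = temporal_composite(
                index_stack(inputs.optical, name), windows[name], reducer
            )
            comp.band_names = [f"{name}_{reducer}"]
            out.s2_indices.append(comp)
    return out


def run_experiment(
    inputs: ExperimentInputs, cfg: ExperimentConfig, progress: bool = False
) -> ExperimentResult:
    """Execute one experiment scheme end to end."""
    composites = build_composites(inputs, cfg)
    feature_stack = assemble_features(cfg.scheme, composites, cfg.glcm)
    if cfg.model == "global":
        label = classify_global(feature_stack, inputs.samples, cfg.classifier)
    elif cfg.model == "tiled":
        grid = make_grid(
            feature_stack.extent, cfg.grid_rows, cfg.grid_cols
        )
        label = classify_tiled(
            feature_stack, grid, inputs.samples, cfg.classifier,
            cfg.per_class_floor, cfg.per_class_cap, progress=progress,
        )
    else:
        raise ParameterError(f"unknown model {cfg.model!r}")
    matrix = confusion(label, inputs.samples)
    report = accuracy_report(matrix)
    provenance = {
        "package": "rectile",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "n_features": feature_stack.n_bands,
        "seed": cfg.classifier.seed,
    }
    return ExperimentResult(report, label, matrix, provenance)


def compare_models(
    result_global: ExperimentResult | AccuracyReport,
    result_tiled: ExperimentResult | AccuracyReport,
) -> dict:
    """Signed metric differences, tiled minus global."""
    ra = result_global.report if isinstance(result_global, ExperimentResult) else result_global
    rb = result_tiled.report if isinstance(result_tiled, ExperimentResult) else result_tiled
    return {
        "oa": rb.oa - ra.oa,
        "kappa": rb.kappa - ra.kappa,
        "f1": {c: rb.f1[c] - ra.f1[c] for c in rb.f1},
    }
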
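"""Shared fixtures: small deterministic rasters and synthetic scenes."""

import datetime as dt

import numpy as np
import pytest

from rectile.raster import RasterStack, SamplePoint, TemporalStack
from rectile.synthetic import (
    SceneSpec,
    SpectralModel,
    default_dates,
    generate_class_map,
    generate_samples,
    generate_scene,
)


@pytest.fixture
def small_stack() -> RasterStack:
    """2-band 10x10 raster on a 10 m grid with one nodata pixel."""
    rng = np.random.default_rng(42)
    vals = rng.random((2, 10, 10)).astype(np.float32)
    mask = np.zeros((10, 10), dtype=bool)
    mask[7, 2] = True
    return RasterStack(
        ["red", "nir"], vals, (500.0, 900.0, 10.0, 10.0), "epsg:32649", mask
    )


@pytest.fixture
def ramp_stack() -> RasterStack:
    """Single band whose value equals the column index; unit pixels at origin."""
    cols = np.tile(np.arange(8, dtype=np.float32), (8, 1))
    return RasterStack(["ramp"], cols[None], (0.0, 8.0, 1.0, 1.0))


def make_temporal(values_per_date, dates=None, band="v", transform=(0.0, 4.0, 1.0, 1.0)):
    """TemporalStack from a list of 2-D arrays (NaN = nodata)."""
    arrays = [np.asarray(v, dtype=np.float32) for v in values_per_date]
    if dates is None:
        dates = [dt.date(2018, 5, 1) + dt.timedelta(days=10 * i)
                 for i in range(len(arrays))]
    entries = [
        (d, RasterStack([band], a[None], transform)) for d, a in zip(dates, arrays)
    ]
    return TemporalStack(entries)


@pytest.fixture(scope="session")
def tiny_scene():
    """Complete 64x64 synthetic scene shared by pipeline-level tests."""
    spec = SceneSpec(shape=(64, 64), patch_scale=8, seed=7)
    class_map = generate_class_map(spec)
    model = SpectralModel(cloud_fraction=0.1)
    dates = default_dates(step_days=15)
    optical, sar, coarse = generate_scene(class_map, model, dates, seed=7)
    samples = generate_samples(class_map, 60, seed=7)
    return {
        "spec": spec,
        "class_map": class_map,
        "model": model,
        "dates": dates,
        "optical": optical,
        "sar": sar,
        "coarse": coarse,
        "samples": samples,
    }
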
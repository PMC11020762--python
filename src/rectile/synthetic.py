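"""Seeded synthetic landscapes for end-to-end pipeline testing.

Generates spatially heterogeneous multi-temporal scenes that emulate the
inputs of an arid-zone grassland-mapping campaign:

* a six-class land-cover map drawn from smoothed Gaussian random fields
  (patchy, fragmented landscape; patch size set by ``patch_scale``);
* an optical reflectance stack (6 canonical bands) with per-class spectra,
  vegetation phenology, optional west-to-east spectral drift, Gaussian
  sensor noise and per-date cloud gaps;
* a SAR-like single-band backscatter stack with multiplicative gamma
  speckle;
* a coarse-resolution stack (block-averaged optical) for index-curve
  window selection.

All randomness flows from one master seed through named substreams, so a
scene is a pure function of its spec.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .classify import LabelRaster
from .errors import ParameterError
from .evaluate import stratified_split
from .raster import CLASSES, RasterStack, SamplePoint, TemporalStack

OPTICAL_BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")

#: per-class mean reflectance, bands in OPTICAL_BANDS order
DEFAULT_SPECTRA: dict[str, tuple[float, ...]] = {
    "cultivated": (0.06, 0.09, 0.08, 0.45, 0.25, 0.15),
    "woodland":   (0.04, 0.07, 0.05, 0.40, 0.18, 0.09),
    "grassland":  (0.06, 0.10, 0.11, 0.30, 0.26, 0.17),
    "waterbody":  (0.08, 0.07, 0.05, 0.03, 0.02, 0.01),
    "building":   (0.18, 0.20, 0.22, 0.28, 0.30, 0.28),
    "unused":     (0.15, 0.20, 0.26, 0.33, 0.42, 0.35),
}

#: per-class mean SAR backscatter (linear power units)
DEFAULT_SAR: dict[str, float] = {
    "cultivated": 0.20,
    "woodland": 0.30,
    "grassland": 0.12,
    "waterbody": 0.02,
    "building": 0.55,
    "unused": 0.08,
}

#: (green-up day-of-year, senescence day-of-year) per vegetated class
DEFAULT_PHENOLOGY: dict[str, tuple[int, int]] = {
    "cultivated": (140, 270),
    "woodland": (130, 300),
    "grassland": (150, 280),
}

#: how strongly greenness scales each band (exponent on the seasonal factor):
#: NIR rises with green vegetation, visible/SWIR reflectance falls.
PHENOLOGY_BAND_WEIGHT = (-0.3, -0.2, -0.6, 1.0, -0.3, -0.4)

#: semi-arid steppe mix: grassland-dominated, large bare-soil fraction
DEFAULT_MIX = (0.14, 0.08, 0.40, 0.05, 0.05, 0.28)


@dataclass
class SceneSpec:
    """Geometry and composition of a synthetic landscape."""

    shape: tuple[int, int] = (256, 256)
    n_classes: int = 6
    patch_scale: float = 25.0
    class_mix: tuple[float, ...] = DEFAULT_MIX
    pixel_size: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_scale < 1:
            raise ParameterError("patch_scale must be >= 1 pixel")
        if not 2 <= self.n_classes <= len(CLASSES):
            raise ParameterError(f"n_classes must be in 2..{len(CLASSES)}")
        mix = np.asarray(self.class_mix, dtype=float)
        if len(mix) != self.n_classes:
            raise ParameterError("class_mix length must equal n_classes")
        if abs(mix.sum() - 1.0) > 0.05:
            warnings.warn("class_mix does not sum to 1; renormalizing")
        self.class_mix = tuple(mix / mix.sum())

    @property
    def transform(self) -> tuple[float, float, float, float]:
        rows, _ = self.shape
        return (0.0, rows * self.pixel_size, self.pixel_size, self.pixel_size)

    @property
    def classes(self) -> tuple[str, ...]:
        return CLASSES[: self.n_classes]


@dataclass
class SpectralModel:
    """Radiometric model mapping classes to multi-temporal pixel values.

    ``drift`` is a per-band additive mean shift per unit normalized easting
    (x = 0 at the west edge, 1 at the east edge), emulating a climatic
    gradient that breaks the stationarity assumed by a single global
    classifier.  ``speckle_looks`` is the gamma shape of the multiplicative
    SAR noise (mean 1, variance 1/looks).  ``cloud_fraction`` is the
    per-date, per-pixel probability of a cloud gap in the optical stack.
    """

    class_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRA)
    )
    noise_sd: float = 0.02
    drift: tuple[float, ...] = (0.0,) * 6
    phenology: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOLOGY)
    )
    phenology_base: float = 0.75
    phenology_amplitude: float = 0.5
    phenology_rate_days: float = 10.0
    sar_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SAR))
    speckle_looks: float = 5.0
    cloud_fraction: float = 0.0
    coarse_factor: int = 16
    #: days by which green-up/senescence shift per unit easting (centered)
    phenology_shift_days: float = 0.0
    #: relative change of seasonal amplitude per unit easting (centered):
    #: amplitude(x) = amplitude * (1 + drift * (x - 0.5)); a positive value
    #: makes western vegetation nearly aseasonal (arid) and eastern
    #: vegetation strongly seasonal
    phenology_amplitude_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.cloud_fraction < 1:
            raise ParameterError("cloud_fraction must be in [0, 1)")

    def seasonal_factor(
        self, cls: str, date: _dt.date, x_norm: float | np.ndarray = 0.5
    ) -> float | np.ndarray:
        """Double-logistic greenness factor (1.0 for non-vegetated classes).

        With a nonzero ``phenology_shift_days`` the green-up and senescence
        dates are delayed by ``shift * (x_norm - 0.5)`` days, emulating a
        phenological gradient across the extent.
        """
        if cls not in self.phenology:
            return np.ones_like(np.asarray(x_norm, dtype=float)) if isinstance(
                x_norm, np.ndarray
            ) else 1.0
        green_up, senescence = self.phenology[cls]
        x = np.asarray(x_norm, dtype=float)
        delay = self.phenology_shift_days * (x - 0.5)
        amp = self.phenology_amplitude * np.clip(
            1.0 + self.phenology_amplitude_drift * (x - 0.5), 0.0, None
        )
        doy = date.timetuple().tm_yday
        r = self.phenology_rate_days
        rise = 1.0 / (1.0 + np.exp(-(doy - (green_up + delay)) / r))
        fall = 1.0 / (1.0 + np.exp(-(doy - (senescence + delay)) / r))
        out = self.phenology_base + amp * (rise - fall)
        return out if isinstance(x_norm, np.ndarray) else float(out)


def drifted_model(
    strength: float = 2.0,
    phenology_shift_days: float = 30.0,
    phenology_amplitude_drift: float = -1.6,
    **kwargs,
) -> SpectralModel:
    """Spectral model with a west-to-east environmental gradient.

    The per-band drift points along the grassland-to-bare-soil (unused)
    spectral difference — the axis along which an aridity gradient moves
    vegetated spectra — scaled so the within-class mean shift across the
    full extent equals ``strength`` such between-class separations.  At the
    default strength 2, grassland in the east occupies the spectral space
    of bare soil half an extent to the west, so a single global classifier
    cannot be simultaneously right everywhere while any local window stays
    separable.  The phenological signature drifts too: green-up and
    senescence shift by ``phenology_shift_days`` across the extent and the
    seasonal amplitude fades toward the east (negative
    ``phenology_amplitude_drift``), so eastern grassland — whose drifted
    spectrum already occupies bare-soil space — is also nearly aseasonal,
    resembling bare soil in both spectrum and trajectory while remaining
    locally separable.
    """
    sep = np.array(DEFAULT_SPECTRA["unused"]) - np.array(
        DEFAULT_SPECTRA["grassland"]
    )
    return SpectralModel(
        drift=tuple(strength * sep),
        phenology_shift_days=phenology_shift_days,
        phenology_amplitude_drift=phenology_amplitude_drift,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Class-map generation
# ---------------------------------------------------------------------------

def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_class_map(spec: SceneSpec) -> LabelRaster:
    """Patchy class map from smoothed Gaussian random fields.

    One standardized random field per class (Gaussian smoothing length =
    ``patch_scale``) plus a per-class offset calibrated so the realized
    class fractions approach ``class_mix``; the label at each pixel is the
    argmax field.  Deterministic in ``spec.seed``.
    """
    rng = _substreams(spec.seed, 4)[0]
    rows, cols = spec.shape
    k = spec.n_classes
    fields = rng.standard_normal((k, rows, cols))
    for i in range(k):
        fields[i] = gaussian_filter(fields[i], sigma=spec.patch_scale, mode="reflect")
        sd = fields[i].std()
        if sd > 0:
            fields[i] /= sd
    target = np.asarray(spec.class_mix)
    offsets = np.zeros(k)
    for _ in range(80):
        labels = np.argmax(fields + offsets[:, None, None], axis=0)
        realized = np.bincount(labels.ravel(), minlength=k) / labels.size
        err = target - realized
        if np.abs(err).max() < 0.002:
            break
        offsets += 1.5 * err
        offsets -= offsets.mean()
    labels = np.argmax(fields + offsets[:, None, None], axis=0)
    return LabelRaster(labels.astype(np.int16), spec.transform, CLASSES)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def generate_scene(
    class_map: LabelRaster,
    model: SpectralModel,
    dates: Sequence[_dt.date],
    seed: int = 0,
) -> tuple[TemporalStack, TemporalStack, TemporalStack]:
    """Optical, SAR and coarse temporal stacks for a class map.

    Optical pixel value: ``(mu_kb + drift_b * x_norm) * f_k(date)^w_b``
    plus Gaussian noise, clipped to [0, 1], where ``f_k`` is the class's
    seasonal greenness factor and ``w_b`` the band's greenness exponent.
    SAR value: class backscatter times a gamma speckle draw.  The coarse
    stack is the optical stack block-averaged by ``model.coarse_factor``.
    """
    dates = list(dates)
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ParameterError("dates must be strictly increasing")
    classes = [c for c in CLASSES if int((class_map.labels == CLASSES.index(c)).sum())]
    for c in classes:
        if c not in model.class_means:
            raise ParameterError(f"class {c!r} missing from spectral model")
    rng_noise, rng_cloud, rng_speckle = _substreams(seed, 3)
    labels = class_map.labels
    rows, cols = labels.shape
    mu = np.array([model.class_means[c] for c in CLASSES])  # (K, 6)
    w = np.asarray(PHENOLOGY_BAND_WEIGHT)
    drift = np.asarray(model.drift)
    x_norm = (np.arange(cols) + 0.5) / cols
    transform = class_map.transform

    optical_entries, sar_entries, coarse_entries = [], [], []
    from .raster import resample_to

    for date in dates:
        # per (class, column) seasonal factor, then band exponents
        f = np.stack(
            [np.broadcast_to(
                model.seasonal_factor(c, date, x_norm), (cols,)
            ) for c in CLASSES]
        )  # (K, cols)
        factor = f[:, :, None] ** w[None, None, :]  # (K, cols, 6)
        base = mu[labels]  # (rows, cols, 6)
        base = base + drift[None, None, :] * x_norm[None, :, None]
        vals = base * factor[labels, np.arange(cols)[None, :], :]
        if model.noise_sd > 0:
            vals = vals + rng_noise.normal(0.0, model.noise_sd, vals.shape)
        vals = np.clip(vals, 0.0, 1.0).transpose(2, 0, 1).astype(np.float32)
        mask = np.zeros((rows, cols), dtype=bool)
        if model.cloud_fraction > 0:
            mask = rng_cloud.random((rows, cols)) < model.cloud_fraction
        optical = RasterStack(
            list(OPTICAL_BANDS), vals, transform, class_map.crs_tag, mask
        )
        optical_entries.append((date, optical))
        coarse_entries.append(
            (date, resample_to(
                optical, transform[2] * model.coarse_factor, "average"
            ))
        )
        sar_mu = np.array([model.sar_means[c] for c in CLASSES])[labels]
        looks = model.speckle_looks
        speckle = rng_speckle.gamma(looks, 1.0 / looks, (rows, cols))
        sar = RasterStack(
            ["VV"], (sar_mu * speckle)[None].astype(np.float32),
            transform, class_map.crs_tag,
        )
        sar_entries.append((date, sar))

    return (
        TemporalStack(optical_entries, "optical"),
        TemporalStack(sar_entries, "sar"),
        TemporalStack(coarse_entries, "coarse"),
    )


def generate_samples(
    class_map: LabelRaster,
    n_per_class: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> list[SamplePoint]:
    """Stratified random sample points at pixel centers of the class map.

    Draws up to ``n_per_class`` pixels per class without replacement (with a
    warning when a class has fewer pixels), then applies a seeded
    class-stratified train/validation split.
    """
    rng_pick, rng_split = _substreams(seed, 2)
    ox, oy, px, py = class_map.transform
    points: list[SamplePoint] = []
    for ci, cls in enumerate(class_map.legend):
        rr, cc = np.nonzero(class_map.labels == ci)
        if rr.size == 0:
            continue
        n = min(n_per_class, rr.size)
        if n < n_per_class:
            warnings.warn(
                f"class {cls!r}: only {rr.size} pixels for {n_per_class} samples"
            )
        take = rng_pick.choice(rr.size, size=n, replace=False)
        for j in take:
            x = ox + (cc[j] + 0.5) * px
            y = oy - (rr[j] + 0.5) * py
            points.append(SamplePoint(x, y, cls, "train"))
    split_seed = int(rng_split.integers(0, 2**31 - 1))
    return stratified_split(points, train_fraction, split_seed)


def default_dates(
    start: str = "2018-05-01", end: str = "2018-11-02", step_days: int = 10
) -> list[_dt.date]:
    """Regular acquisition calendar between two ISO dates."""
    d0 = _dt.date.fromisoformat(start)
    d1 = _dt.date.fromisoformat(end)
    out = []
    d = d0
    while d <= d1:
        out.append(d)
        d += _dt.timedelta(days=step_days)
    return out
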
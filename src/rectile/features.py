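"""Feature engineering: spectral indices, GLCM textures, feature stacks.

The classifier consumes five feature blocks:

* ``s1_pol``  — monthly SAR backscatter (VV) median composites (6 bands),
* ``s1_tex``  — 4 GLCM textures per monthly SAR composite (24 bands),
* ``s2_spec`` — 6 optical reflectance bands per seasonal period (12 bands),
* ``s2_vi``   — 4 single vegetation-index composites (NDVI-max, MSAVI-max,
  NDWI-min, NDBI-min),
* ``s2_tex``  — 4 GLCM textures on red and NIR per period (16 bands),

combined into seven nested experiment schemes (EXP1..EXP7) with 6, 30, 12,
16, 32, 46 and 62 feature bands respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.ndimage import uniform_filter

from .errors import AssemblyError, ParameterError, SchemaError
from .raster import RasterStack, concat_stacks

INDEX_NAMES = ("NDVI", "MSAVI", "NDWI", "NDBI")

#: bands required per index (canonical optical band names)
_INDEX_BANDS = {
    "NDVI": ("nir", "red"),
    "MSAVI": ("nir", "red"),
    "NDWI": ("green", "nir"),
    "NDBI": ("swir1", "nir"),
}

TEXTURE_NAMES = ("ASM", "CON", "COR", "ENT")

#: Table of experiment schemes: name -> ordered feature blocks
SCHEME_BLOCKS: dict[str, tuple[str, ...]] = {
    "EXP1": ("s1_pol",),
    "EXP2": ("s1_pol", "s1_tex"),
    "EXP3": ("s2_spec",),
    "EXP4": ("s2_spec", "s2_vi"),
    "EXP5": ("s2_spec", "s2_vi", "s2_tex"),
    "EXP6": ("s1_pol", "s1_tex", "s2_spec", "s2_vi"),
    "EXP7": ("s1_pol", "s1_tex", "s2_spec", "s2_vi", "s2_tex"),
}

SCHEME_COUNTS: dict[str, int] = {
    "EXP1": 6,
    "EXP2": 30,
    "EXP3": 12,
    "EXP4": 16,
    "EXP5": 32,
    "EXP6": 46,
    "EXP7": 62,
}


@dataclass(frozen=True)
class FeatureScheme:
    """A named combination of feature blocks with its expected band count."""

    name: str
    blocks: tuple[str, ...]
    expected_count: int

    @staticmethod
    def by_name(name: str) -> "FeatureScheme":
        if name not in SCHEME_BLOCKS:
            raise ParameterError(
                f"unknown scheme {name!r}; expected one of {sorted(SCHEME_BLOCKS)}"
            )
        return FeatureScheme(name, SCHEME_BLOCKS[name], SCHEME_COUNTS[name])


@dataclass(frozen=True)
class GlcmParams:
    """Sliding-window gray-level co-occurrence parameters.

    Defaults: 7x7 window (radius 3), 32 gray levels, the four standard
    offsets pooled, symmetric counting, natural-log entropy.
    """

    window_radius: int = 3
    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ParameterError("GLCM needs at least 2 gray levels")
        if self.window_radius < 1:
            raise ParameterError("window radius must be >= 1")


# ---------------------------------------------------------------------------
# Spectral indices
# ---------------------------------------------------------------------------

def compute_index(stack: RasterStack, index_name: str) -> RasterStack:
    """Normalized-difference / soil-adjusted index as a single-band stack.

    NDVI = (NIR-R)/(NIR+R); NDWI = (G-NIR)/(G+NIR);
    NDBI = (SWIR1-NIR)/(SWIR1+NIR);
    MSAVI = (2*NIR + 1 - sqrt((2*NIR+1)^2 - 8*(NIR-R))) / 2.

    Zero-denominator (or negative-discriminant) pixels become nodata.
    """
    if index_name not in _INDEX_BANDS:
        raise ParameterError(f"unknown index {index_name!r}")
    req = _INDEX_BANDS[index_name]
    for b in req:
        if b not in stack.band_names:
            raise SchemaError(
                f"{index_name} needs band {b!r}; stack has {stack.band_names}"
            )
    with np.errstate(all="ignore"):
        if index_name == "NDVI":
            nir, red = stack.band("nir"), stack.band("red")
            out = (nir - red) / (nir + red)
        elif index_name == "NDWI":
            green, nir = stack.band("green"), stack.band("nir")
            out = (green - nir) / (green + nir)
        elif index_name == "NDBI":
            swir1, nir = stack.band("swir1"), stack.band("nir")
            out = (swir1 - nir) / (swir1 + nir)
        else:  # MSAVI
            nir, red = stack.band("nir"), stack.band("red")
            disc = (2 * nir + 1) ** 2 - 8 * (nir - red)
            out = np.where(disc >= 0, (2 * nir + 1 - np.sqrt(np.abs(disc))) / 2,
                           np.nan)
    mask = stack.nodata_mask | ~np.isfinite(out)
    return stack.with_values([index_name], out[None], mask)


# ---------------------------------------------------------------------------
# GLCM textures
# ---------------------------------------------------------------------------

def quantize(band: RasterStack, levels: int) -> RasterStack:
    """Equal-width gray-level binning between the band's valid min and max.

    The valid maximum maps to ``levels - 1``; a constant band maps to all
    zeros.  Output values are integer levels stored in the raster payload;
    nodata is preserved.
    """
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    if band.n_bands != 1:
        raise ParameterError("quantize expects a single-band stack")
    vals = band.masked()[0]
    if not np.isfinite(vals).any():
        raise ParameterError("band has no valid pixels")
    vmin, vmax = np.nanmin(vals), np.nanmax(vals)
    if vmax == vmin:
        q = np.zeros_like(vals)
    else:
        q = np.floor((vals - vmin) / (vmax - vmin) * levels)
        q = np.clip(q, 0, levels - 1)
    return band.with_values(band.band_names, q[None])


def _window_sum(x: np.ndarray, size: int) -> np.ndarray:
    return uniform_filter(x, size=size, mode="constant", cval=0.0) * size * size


def glcm_features(band: RasterStack, params: GlcmParams = GlcmParams()) -> RasterStack:
    """Per-pixel GLCM texture measures: ASM, CON, COR, ENT.

    For each pixel, pairs of quantized gray levels at the configured offsets
    are counted over the surrounding window (anchored at the first pixel of
    each pair), pooled over offsets, optionally symmetrized, and normalized
    into a co-occurrence distribution P.  Then

    * ASM = sum P^2                  (angular second moment, uniformity)
    * CON = sum P * (i-j)^2          (contrast, local gray-level variation)
    * COR = cov(i,j) / (sd_i * sd_j) (correlation; 0 where a margin is flat)
    * ENT = -sum P ln P              (entropy, with 0 ln 0 = 0)

    Pairs involving nodata pixels are excluded; pixels with no valid pair in
    their window are nodata in the output.
    """
    if band.n_bands != 1:
        raise ParameterError("glcm_features expects a single quantized band")
    rows, cols = band.shape
    size = 2 * params.window_radius + 1
    if size > rows or size > cols:
        raise ParameterError(
            f"{size}x{size} window does not fit a {rows}x{cols} raster"
        )
    q = np.nan_to_num(band.values[0], nan=0.0).astype(np.int64)
    if q.min() < 0 or q.max() >= params.levels:
        raise ParameterError("band is not quantized to params.levels")
    valid = ~band.nodata_mask

    # Per ordered code (i, j): window counts of pairs anchored at each pixel,
    # pooled over offsets.
    cnts: dict[tuple[int, int], np.ndarray] = {}
    total = np.zeros((rows, cols))
    for drow, dcol in params.offsets:
        vi = np.zeros((rows, cols), dtype=bool)
        pj = np.zeros((rows, cols), dtype=np.int64)
        src_r = slice(max(0, -drow), rows - max(0, drow))
        src_c = slice(max(0, -dcol), cols - max(0, dcol))
        dst_r = slice(max(0, drow), rows - max(0, -drow))
        dst_c = slice(max(0, dcol), cols - max(0, -dcol))
        vi[src_r, src_c] = valid[src_r, src_c] & valid[dst_r, dst_c]
        pj[src_r, src_c] = q[dst_r, dst_c]
        total += _window_sum(vi.astype(np.float64), size)
        codes = np.unique(
            np.stack([q[vi], pj[vi]], axis=1), axis=0
        ) if vi.any() else np.empty((0, 2), dtype=np.int64)
        for i, j in codes:
            ind = (vi & (q == i) & (pj == j)).astype(np.float64)
            key = (int(i), int(j))
            s = _window_sum(ind, size)
            cnts[key] = cnts.get(key, 0) + s

    if params.symmetric:
        keys = set(cnts) | {(j, i) for i, j in cnts}
        entries = {
            k: (cnts.get(k, 0.0) + cnts.get((k[1], k[0]), 0.0)) for k in keys
        }
        norm = 2.0 * total
    else:
        entries = dict(cnts)
        norm = total

    asm = np.zeros((rows, cols))
    con = np.zeros((rows, cols))
    ent = np.zeros((rows, cols))
    si = np.zeros((rows, cols))
    sj = np.zeros((rows, cols))
    si2 = np.zeros((rows, cols))
    sj2 = np.zeros((rows, cols))
    sij = np.zeros((rows, cols))
    ok = norm > 0
    with np.errstate(all="ignore"):
        for (i, j), cnt in entries.items():
            p = np.where(ok, cnt / np.where(ok, norm, 1.0), 0.0)
            asm += p * p
            con += p * (i - j) ** 2
            pos = p > 0
            ent -= np.where(pos, p * np.log(np.where(pos, p, 1.0)), 0.0)
            si += i * p
            sj += j * p
            si2 += i * i * p
            sj2 += j * j * p
            sij += i * j * p
        var_i = si2 - si * si
        var_j = sj2 - sj * sj
        denom = np.sqrt(np.clip(var_i, 0, None) * np.clip(var_j, 0, None))
        cor = np.where(denom > 1e-12, (sij - si * sj) / np.where(denom > 0, denom, 1.0), 0.0)

    out = np.stack([asm, con, cor, ent])
    mask = band.nodata_mask | ~ok
    out[:, mask] = np.nan
    return band.with_values(list(TEXTURE_NAMES), out, mask)


# ---------------------------------------------------------------------------
# Feature-stack assembly
# ---------------------------------------------------------------------------

@dataclass
class CompositeSet:
    """Named composite inputs from which feature blocks are built.

    Attributes
    ----------
    s1_monthly
        Monthly SAR composites (single ``VV``-like band each; 6 by default).
    s2_periods
        Seasonal optical composites (canonical 6 reflectance bands each;
    growth and senescence periods by default).
    s2_indices
        Single-band vegetation-index composites (4: NDVI-max, MSAVI-max,
        NDWI-min, NDBI-min).
    """

    s1_monthly: list[RasterStack] = field(default_factory=list)
    s2_periods: list[RasterStack] = field(default_factory=list)
    s2_indices: list[RasterStack] = field(default_factory=list)


def _texture_stack(
    source: RasterStack, band_name: str, params: GlcmParams
) -> RasterStack:
    qband = quantize(source.select([band_name]), params.levels)
    tex = glcm_features(qband, params)
    tex.band_names = [f"{band_name}_{t}" for t in TEXTURE_NAMES]
    return tex


def _prefix(stack: RasterStack, block: str) -> RasterStack:
    stack.band_names = [f"{block}/{n}" for n in stack.band_names]
    return stack


def assemble_features(
    scheme: FeatureScheme | str,
    composites: CompositeSet,
    glcm: GlcmParams = GlcmParams(),
    texture_bands: tuple[str, str] = ("red", "nir"),
) -> RasterStack:
    """Build the feature stack for one experiment scheme.

    Textures are computed on demand: one set per monthly SAR composite for
    ``s1_tex`` and one set per (texture band x period) for ``s2_tex``.
    Raises :class:`AssemblyError` naming the offending block if the final
    band count disagrees with the scheme's expected count.
    """
    if isinstance(scheme, str):
        scheme = FeatureScheme.by_name(scheme)
    parts: list[RasterStack] = []
    realized: dict[str, int] = {}
    for block in scheme.blocks:
        if block == "s1_pol":
            if not composites.s1_monthly:
                raise AssemblyError("block s1_pol: no monthly SAR composites")
            sub = [_prefix(s.select(s.band_names), block)
                   for s in composites.s1_monthly]
        elif block == "s1_tex":
            if not composites.s1_monthly:
                raise AssemblyError("block s1_tex: no monthly SAR composites")
            sub = []
            for s in composites.s1_monthly:
                if s.n_bands != 1:
                    raise AssemblyError(
                        "block s1_tex: monthly SAR composites must be single-band"
                    )
                tex = _texture_stack(s, s.band_names[0], glcm)
                sub.append(_prefix(tex, block))
        elif block == "s2_spec":
            if not composites.s2_periods:
                raise AssemblyError("block s2_spec: no period composites")
            sub = []
            for k, s in enumerate(composites.s2_periods, start=1):
                spec = s.select(s.band_names)
                spec.band_names = [f"{n}_p{k}" for n in spec.band_names]
                sub.append(_prefix(spec, block))
        elif block == "s2_vi":
            if not composites.s2_indices:
                raise AssemblyError("block s2_vi: no index composites")
            sub = [_prefix(s.select(s.band_names), block)
                   for s in composites.s2_indices]
        elif block == "s2_tex":
            if not composites.s2_periods:
                raise AssemblyError("block s2_tex: no period composites")
            sub = []
            for k, s in enumerate(composites.s2_periods, start=1):
                for bname in texture_bands:
                    if bname not in s.band_names:
                        raise AssemblyError(
                            f"block s2_tex: period composite lacks band {bname!r}"
                        )
                    tex = _texture_stack(s, bname, glcm)
                    tex.band_names = [f"{n}_p{k}" for n in tex.band_names]
                    sub.append(_prefix(tex, block))
        else:
            raise AssemblyError(f"unknown feature block {block!r}")
        realized[block] = sum(s.n_bands for s in sub)
        parts.extend(sub)
    stack = concat_stacks(parts)
    if stack.n_bands != scheme.expected_count:
        raise AssemblyError(
            f"scheme {scheme.name}: assembled {stack.n_bands} bands, "
            f"expected {scheme.expected_count}; per block: {realized}"
        )
    return stack
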
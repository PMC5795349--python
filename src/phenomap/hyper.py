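"""Hyperspectral cube processing: NDVI/stem segmentation, normalization, PCA.

A cube is a stack of single-band grayscale planes with a strictly increasing
wavelength grid (by default 243 bands spanning 546-1700 nm).  Plant pixels
are found with NDVI = (R750-R705)/(R750+R705) > 0.25; within the plant, stem
pixels satisfy R1056/R1151 > 1.2 and leaf pixels are the remainder, so stem
and leaf always partition the plant mask exactly.  Because lamp performance
drifts between images, plant-pixel intensities are normalized per band by
the mean intensity of the non-plant pixels of the same image, which cancels
any global illumination scalar.  For visualization, a pixel-level PCA over
normalized plant spectra is rendered as a false-color image (PC1 red, PC2
green, PC3 blue, each min-max rescaled over the pooled pixels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from sklearn.decomposition import PCA

from .rgb import PlantMask

NDVI_THRESHOLD = 0.25
STEM_RATIO_THRESHOLD = 1.2
DEFAULT_BAND_COUNT = 243
DEFAULT_WAVELENGTH_RANGE = (546.0, 1700.0)

NDVI_NIR_NM = 750.0
NDVI_RED_EDGE_NM = 705.0
STEM_NUM_NM = 1056.0
STEM_DEN_NM = 1151.0


def default_wavelength_grid(
    band_count: int = DEFAULT_BAND_COUNT,
    wavelength_range_nm: tuple[float, float] = DEFAULT_WAVELENGTH_RANGE,
) -> np.ndarray:
    """Uniform band-center grid over the instrument's spectral range."""
    lo, hi = wavelength_range_nm
    if band_count < 2:
        raise ValueError("a cube needs at least 2 bands")
    if not lo < hi:
        raise ValueError("wavelength range must be strictly increasing")
    return np.linspace(lo, hi, band_count)


@dataclass(frozen=True)
class HyperCube:
    planes: np.ndarray  # (bands, H, W)
    wavelengths_nm: np.ndarray  # (bands,) strictly increasing
    normalized: bool = False  # True after background normalization

    def __post_init__(self) -> None:
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (bands, H, W) stack")
        if self.planes.shape[0] < 2:
            raise ValueError("a cube needs at least 2 bands")
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.shape != (self.planes.shape[0],):
            raise ValueError("one wavelength per band required")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def n_bands(self) -> int:
        return int(self.planes.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def band(self, target_nm: float) -> np.ndarray:
        return self.planes[band_for_wavelength(self, target_nm)].astype(np.float64)


@dataclass(frozen=True)
class SpectralSummary:
    tissue: str  # stem | leaf | plant
    mean_intensity: np.ndarray
    n_pixels: int
    wavelengths_nm: np.ndarray


def band_for_wavelength(cube: HyperCube, target_nm: float) -> int:
    """Index of the band center nearest to ``target_nm``; ties go low."""
    wl = cube.wavelengths_nm
    if not (wl[0] <= target_nm <= wl[-1]):
        raise ValueError(
            f"{target_nm} nm outside cube range {wl[0]:.1f}-{wl[-1]:.1f} nm"
        )
    return int(np.argmin(np.abs(wl - target_nm)))


# ---------------------------------------------------------------------------
# disk dialect: one grayscale image per wavelength folder (Day_NN/<nm>/)

_BAND_FILE = "band.png"


def write_cube(cube: HyperCube, directory) -> None:
    """Write one grayscale PNG per band into integer-nm wavelength folders."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    planes = cube.planes
    if planes.dtype != np.uint8:
        planes = np.clip(np.round(planes), 0, 255).astype(np.uint8)
    for k, wl in enumerate(cube.wavelengths_nm):
        sub = directory / str(int(round(wl)))
        sub.mkdir(exist_ok=True)
        iio.imwrite(sub / _BAND_FILE, planes[k])


def read_cube(directory, wavelengths_nm: Sequence[float] | None = None) -> HyperCube:
    """Read a cube from a day directory of per-wavelength folders.

    Folder names carry the (rounded) band wavelength in nm and define band
    order; pass ``wavelengths_nm`` to restore an exact non-integer grid.
    Grayscale bands stored as 3-channel images with identical channels are
    accepted and collapsed to a single channel.
    """
    directory = Path(directory)
    subs = sorted(
        (d for d in directory.iterdir() if d.is_dir() and re.fullmatch(r"\d+", d.name)),
        key=lambda d: int(d.name),
    )
    if len(subs) < 2:
        raise ValueError(f"no wavelength folders found under {directory}")
    if wavelengths_nm is not None and len(wavelengths_nm) != len(subs):
        missing = set(int(round(w)) for w in wavelengths_nm) - set(
            int(d.name) for d in subs
        )
        raise ValueError(
            f"expected {len(wavelengths_nm)} bands, found {len(subs)}; "
            f"missing wavelengths (nm): {sorted(missing)}"
        )
    planes = []
    for d in subs:
        f = d / _BAND_FILE
        if not f.exists():
            raise FileNotFoundError(f"missing band file for wavelength {d.name} nm")
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # 3-channel grayscale: all channels identical
            img = img[..., 0]
        planes.append(img)
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent band dimensions: {sorted(shapes)}")
    wl = (
        np.asarray(wavelengths_nm, dtype=float)
        if wavelengths_nm is not None
        else np.array([int(d.name) for d in subs], dtype=float)
    )
    return HyperCube(np.stack(planes), wl)


# ---------------------------------------------------------------------------
# segmentation


def ndvi(cube: HyperCube) -> np.ndarray:
    """Per-pixel NDVI from the bands nearest 750 and 705 nm; 0/0 -> 0."""
    nir = cube.band(NDVI_NIR_NM)
    red = cube.band(NDVI_RED_EDGE_NM)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def segment_plant_ndvi(cube: HyperCube, threshold: float = NDVI_THRESHOLD) -> PlantMask:
    """Plant mask: NDVI strictly greater than ``threshold``."""
    return PlantMask(ndvi(cube) > threshold)


def stem_ratio(cube: HyperCube) -> np.ndarray:
    """Per-pixel R1056/R1151; zero denominator maps to +inf (numerator > 0) or 0."""
    num = cube.band(STEM_NUM_NM)
    den = cube.band(STEM_DEN_NM)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    ratio = np.where((den == 0) & (num > 0), np.inf, ratio)
    return ratio


def segment_stem(
    cube: HyperCube,
    plant_mask: PlantMask,
    threshold: float = STEM_RATIO_THRESHOLD,
) -> tuple[PlantMask, PlantMask]:
    """Split the plant mask into (stem, leaf) by the R1056/R1151 ratio.

    Stem = plant pixels whose ratio exceeds ``threshold`` strictly; leaf is
    every remaining plant pixel, so the two always partition the plant mask.
    """
    stem = plant_mask.mask & (stem_ratio(cube) > threshold)
    leaf = plant_mask.mask & ~stem
    return PlantMask(stem), PlantMask(leaf)


def segment_naive(cube: HyperCube, ndvi_threshold=NDVI_THRESHOLD,
                  stem_threshold=STEM_RATIO_THRESHOLD) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel loop oracle for NDVI and stem-ratio segmentation (tests only)."""
    nir = cube.band(NDVI_NIR_NM)
    red = cube.band(NDVI_RED_EDGE_NM)
    num = cube.band(STEM_NUM_NM)
    den = cube.band(STEM_DEN_NM)
    h, w = cube.shape
    plant = np.zeros((h, w), bool)
    stem = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            s = nir[i, j] + red[i, j]
            v = (nir[i, j] - red[i, j]) / s if s > 0 else 0.0
            plant[i, j] = v > ndvi_threshold
            if den[i, j] > 0:
                r = num[i, j] / den[i, j]
            else:
                r = float("inf") if num[i, j] > 0 else 0.0
            stem[i, j] = plant[i, j] and r > stem_threshold
    return plant, stem


# ---------------------------------------------------------------------------
# normalization and summaries


def normalize_cube(
    cube: HyperCube, plant_mask: PlantMask, statistic: str = "mean"
) -> HyperCube:
    """Divide each plant pixel by the per-band background level.

    The background of the same image acts as an internal illumination
    reference: a global lamp-intensity scalar multiplies plant and
    background alike and cancels in the ratio.  The background level is the
    per-band mean of non-plant pixels (``statistic="median"`` switches to
    the median).  Non-plant pixels pass through unchanged; the result is
    flagged as reflectance-like.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    bg = ~plant_mask.mask
    if not bg.any():
        raise ValueError("normalization needs at least one non-plant pixel")
    planes = cube.planes.astype(np.float64)
    reduce = np.mean if statistic == "mean" else np.median
    bg_mean = reduce(planes[:, bg], axis=1)
    zero = np.nonzero(bg_mean == 0)[0]
    if zero.size:
        raise ValueError(
            f"background mean is zero for band index {zero[0]} "
            f"({cube.wavelengths_nm[zero[0]]:.0f} nm)"
        )
    out = planes.copy()
    out[:, plant_mask.mask] = planes[:, plant_mask.mask] / bg_mean[:, None]
    return HyperCube(out, cube.wavelengths_nm, normalized=True)


def mean_spectrum(cube: HyperCube, mask: PlantMask, tissue: str = "plant") -> SpectralSummary:
    """Per-band arithmetic mean intensity over the masked pixels."""
    if mask.is_na:
        raise ValueError("mean_spectrum requires a non-empty mask")
    vals = cube.planes.astype(np.float64)[:, mask.mask]
    return SpectralSummary(
        tissue=tissue,
        mean_intensity=vals.mean(axis=1),
        n_pixels=mask.n_pixels,
        wavelengths_nm=cube.wavelengths_nm,
    )


# ---------------------------------------------------------------------------
# PCA false color


def minmax_rescale(x: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant vector maps to all zeros."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=np.float64)
    return (x - lo) / (hi - lo)


def _quantize(x01: np.ndarray) -> np.ndarray:
    # round half up to 0-255
    return np.floor(x01 * 255.0 + 0.5).astype(np.uint8)


def pca_false_color(
    cubes: Sequence[HyperCube],
    masks: Sequence[PlantMask],
    n_components: int = 3,
) -> tuple[list[np.ndarray], PCA]:
    """False-color renderings of plant-pixel spectral variation.

    PCA is fitted on the pooled plant-pixel x band matrix of all supplied
    cubes (band-centered), so colors are comparable between plants.  Each
    component's scores are min-max rescaled to [0, 1] over the pooled pixels
    and quantized to 8 bits; component 1 fills the red channel, 2 green,
    3 blue.  Non-plant pixels are rendered black.  A component with zero
    spread renders as 0.
    """
    if len(cubes) != len(masks):
        raise ValueError("need one mask per cube")
    cols = [c.planes.astype(np.float64)[:, m.mask].T for c, m in zip(cubes, masks)]
    X = np.concatenate(cols, axis=0)
    if X.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} plant pixels, got {X.shape[0]}"
        )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)  # sklearn centers per band internally
    channels = np.stack([minmax_rescale(scores[:, k]) for k in range(n_components)], axis=1)
    quant = _quantize(channels)
    if quant.shape[1] < 3:
        pad = np.zeros((quant.shape[0], 3 - quant.shape[1]), dtype=np.uint8)
        quant = np.hstack([quant, pad])
    images = []
    start = 0
    for cube, mask in zip(cubes, masks):
        n = mask.n_pixels
        img = np.zeros((*cube.shape, 3), dtype=np.uint8)
        img[mask.mask] = quant[start : start + n, :3]
        images.append(img)
        start += n
    return images, pca
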
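"""RGB plant segmentation and geometric trait extraction.

Plant pixels are separated from the greenhouse background with a green index,
2G/(R+B); pixels strictly above 1.15 count as plant.  Geometric traits come
from the axis-aligned minimum bounding box of the mask (height = y extent,
width = x extent) and the plant-pixel count; physical units use the camera
zoom calibration (0.746 mm/px at zoom 1, 1.507 mm/px at zoom 2), with pixel
areas additionally expressed on the zoom-1 scale so that counts taken at
different zooms are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GREEN_INDEX_THRESHOLD = 1.15
MM_PER_PIXEL_ZOOM1 = 0.746
MM_PER_PIXEL_ZOOM2 = 1.507

VIEWS = ("side0", "side90", "top")


@dataclass(frozen=True)
class RasterImage:
    """8-bit color raster with acquisition metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    view: str = "side0"
    day: int = 0
    zoom: int = 1

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) array")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")


@dataclass(frozen=True)
class PlantMask:
    """Boolean plant-pixel grid; NA when no pixel was classified as plant."""

    mask: np.ndarray  # (H, W) bool

    @property
    def is_na(self) -> bool:
        return not bool(self.mask.any())

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ZoomCalibration:
    mm_per_pixel_zoom1: float = MM_PER_PIXEL_ZOOM1
    mm_per_pixel_zoom2: float = MM_PER_PIXEL_ZOOM2
    zoom_schedule: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mm_per_pixel_zoom1 <= 0 or self.mm_per_pixel_zoom2 <= 0:
            raise ValueError("mm-per-pixel factors must be positive")
        for z in self.zoom_schedule.values():
            if z not in (1, 2):
                raise ValueError("zoom levels must be 1 or 2")

    def zoom_at(self, day: int) -> int:
        return int(self.zoom_schedule.get(day, 1))

    def mm_per_pixel(self, zoom: int) -> float:
        if zoom == 1:
            return self.mm_per_pixel_zoom1
        if zoom == 2:
            return self.mm_per_pixel_zoom2
        raise ValueError(f"unknown zoom level {zoom}")


@dataclass(frozen=True)
class GeometryTraits:
    """Bounding-box and area traits; all NaN together when the mask is NA.

    area_adj is the pixel count rescaled to the zoom-1 pixel footprint,
    area_px * (mm_per_pixel(zoom) / mm_per_pixel_zoom1)**2, so areas from
    the two zoom levels live on a common scale.
    """

    height_px: float
    width_px: float
    area_px: float
    height_mm: float
    width_mm: float
    area_adj: float
    area_mm2: float

    @property
    def is_na(self) -> bool:
        return bool(np.isnan(self.height_px))


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, RasterImage) else np.asarray(image)


def green_index(image) -> np.ndarray:
    """Per-pixel green index 2G/(R+B) as float.

    Degenerate pixels: R+B == 0 with G > 0 maps to +inf (maximally green),
    R+B == 0 with G == 0 maps to 0 (pure black is background).
    """
    px = _as_pixels(image).astype(np.float64)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    denom = r + b
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(denom > 0, 2.0 * g / np.where(denom > 0, denom, 1.0), 0.0)
    idx = np.where((denom == 0) & (g > 0), np.inf, idx)
    return idx


def _validate_rect(rect, shape) -> tuple[int, int, int, int]:
    r0, c0, r1, c1 = (int(v) for v in rect)
    h, w = shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"rectangle {rect} malformed or outside image {shape}")
    return r0, c0, r1, c1


def segment_plant(
    image,
    threshold: float = GREEN_INDEX_THRESHOLD,
    exclusions: Sequence[tuple[int, int, int, int]] = (),
) -> PlantMask:
    """Green-index segmentation with frame-exclusion rectangles.

    A pixel is plant when its green index is strictly greater than
    ``threshold`` and it lies outside every exclusion rectangle
    (rectangles are (row0, col0, row1, col1), half-open).
    """
    idx = green_index(image)
    mask = idx > threshold
    for rect in exclusions:
        r0, c0, r1, c1 = _validate_rect(rect, mask.shape)
        mask[r0:r1, c0:c1] = False
    return PlantMask(mask)


_NA_TRAITS = GeometryTraits(*([float("nan")] * 7))


def extract_geometry(
    mask: PlantMask, calib: ZoomCalibration | None = None, day: int = 0
) -> GeometryTraits:
    """Bounding-box height/width, pixel area, and zoom-corrected physical units.

    Extents are inclusive pixel counts (a plant spanning rows 10..109 is
    100 px tall).  An NA mask yields NaN for every field.
    """
    if mask.is_na:
        return _NA_TRAITS
    calib = calib or ZoomCalibration()
    rows, cols = np.nonzero(mask.mask)
    height_px = float(rows.max() - rows.min() + 1)
    width_px = float(cols.max() - cols.min() + 1)
    area_px = float(mask.n_pixels)
    mmpp = calib.mm_per_pixel(calib.zoom_at(day))
    scale = mmpp / calib.mm_per_pixel_zoom1
    return GeometryTraits(
        height_px=height_px,
        width_px=width_px,
        area_px=area_px,
        height_mm=height_px * mmpp,
        width_mm=width_px * mmpp,
        area_adj=area_px * scale**2,
        area_mm2=area_px * mmpp**2,
    )


def segment_plant_naive(image, threshold: float = GREEN_INDEX_THRESHOLD) -> np.ndarray:
    """Reference per-pixel loop implementation of the green-index rule.

    Kept as an independent oracle for the vectorized path; do not use on
    large images.
    """
    px = _as_pixels(image)
    h, w = px.shape[:2]
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (float(px[i, j, k]) for k in range(3))
            denom = r + b
            if denom == 0:
                gi = float("inf") if g > 0 else 0.0
            else:
                gi = 2.0 * g / denom
            out[i, j] = gi > threshold
    return out


_TRAIT_COLUMNS = [
    "height_px",
    "width_px",
    "area_px",
    "height_mm",
    "width_mm",
    "area_adj",
    "area_mm2",
]


def build_trait_timeseries(
    index: pd.DataFrame,
    calib: ZoomCalibration | None = None,
    threshold: float = GREEN_INDEX_THRESHOLD,
    exclusions: Sequence[tuple[int, int, int, int]] = (),
) -> pd.DataFrame:
    """Extract geometry traits for every indexed RGB image.

    ``index`` is a dataset index (see :func:`phenomap.dataset.index_dataset`)
    restricted here to its RGB records.  Returns a long table keyed by
    (plant, genotype, day, view, trait); unreadable images produce NA rows
    with a logged warning, and the top view is reported in pixels only (no
    published mm calibration exists for it).
    """
    calib = calib or ZoomCalibration()
    recs = index[index["camera"] == "RGB"]
    if recs.empty:
        raise ValueError("index contains no RGB records")
    out: list[dict] = []
    n_failed = 0
    for rec in recs.itertuples():
        try:
            px = iio.imread(rec.path)
            traits = extract_geometry(
                segment_plant(px[..., :3], threshold, exclusions), calib, rec.day
            )
        except (OSError, ValueError) as exc:
            log.warning("failed to process %s: %s", rec.path, exc)
            n_failed += 1
            traits = _NA_TRAITS
        for name in _TRAIT_COLUMNS:
            if rec.view == "top" and name.endswith(("_mm", "_mm2", "_adj")):
                continue
            out.append(
                {
                    "plant": rec.plant,
                    "genotype": rec.genotype,
                    "day": rec.day,
                    "view": rec.view,
                    "trait": name,
                    "value": getattr(traits, name),
                }
            )
    if n_failed == len(recs):
        raise RuntimeError("all RGB images failed to load")
    if n_failed:
        warnings.warn(f"{n_failed} RGB images could not be processed; NA rows emitted")
    return pd.DataFrame(out)
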
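"""Fluorescence image processing.

Chlorophyll fluorescence is recorded almost entirely in the red channel of
the camera's 8-bit output.  Within a zoom-specific region of interest (set
to exclude the pot and non-uniform backdrop), pixels with red intensity
strictly greater than 70 are plant pixels; the aggregate fluorescence
intensity is the sum of their red values and the mean intensity is the
aggregate divided by the pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rgb import PlantMask, RasterImage, _as_pixels, _validate_rect

FLUOR_THRESHOLD = 70


@dataclass(frozen=True)
class FluorResult:
    aggregate_intensity: float
    mean_intensity: float
    n_pixels: int

    @property
    def is_na(self) -> bool:
        return self.n_pixels == 0


NA_FLUOR = FluorResult(float("nan"), float("nan"), 0)


def segment_fluorescence(
    image,
    roi: tuple[int, int, int, int] | None = None,
    threshold: int = FLUOR_THRESHOLD,
) -> PlantMask:
    """Plant mask: red channel strictly above ``threshold``, inside ``roi``.

    ``roi`` is a (row0, col0, row1, col1) half-open rectangle; ``None``
    means the whole frame.
    """
    px = _as_pixels(image)
    red = px[..., 0] if px.ndim == 3 else px
    mask = red.astype(np.int64) > threshold
    if roi is not None:
        r0, c0, r1, c1 = _validate_rect(roi, mask.shape)
        keep = np.zeros_like(mask)
        keep[r0:r1, c0:c1] = True
        mask &= keep
    return PlantMask(mask)


def fluorescence_intensity(mask: PlantMask, image) -> FluorResult:
    """Aggregate and mean red-channel intensity over the plant mask."""
    px = _as_pixels(image)
    red = px[..., 0] if px.ndim == 3 else px
    if red.shape != mask.mask.shape:
        raise ValueError("mask and image dimensions differ")
    if mask.is_na:
        return NA_FLUOR
    agg = float(red[mask.mask].astype(np.int64).sum())
    n = mask.n_pixels
    return FluorResult(aggregate_intensity=agg, mean_intensity=agg / n, n_pixels=n)
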
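"""Pipeline configuration: thresholds, calibration, regions, seeds."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .rgb import GREEN_INDEX_THRESHOLD, MM_PER_PIXEL_ZOOM1, MM_PER_PIXEL_ZOOM2

# calendar anchors of the original experiment, used by the zoom preset
SOWING_DATE = dt.date(2015, 10, 2)
DEFAULT_IMAGING_START = dt.date(2015, 10, 13)
_ZOOM2_DATES = {dt.date(2015, 10, 20)} | {
    dt.date(2015, 11, d) for d in range(5, 11)
}


def paper_zoom_schedule(
    imaging_start: dt.date = DEFAULT_IMAGING_START, n_days: int = 29
) -> dict[int, int]:
    """Day-index -> zoom map reproducing the experiment's zoom history.

    The side-view camera ran at zoom 1 except on 20 Oct 2015 (a system
    error) and from 5 Nov 2015 onward (zoom reduced to keep tall plants in
    frame), where each pixel spans 1.507 mm instead of 0.746 mm.  Day 1 is
    ``imaging_start``.
    """
    out = {}
    for day in range(1, n_days + 1):
        date = imaging_start + dt.timedelta(days=day - 1)
        out[day] = 2 if date in _ZOOM2_DATES else 1
    return out


@dataclass
class PipelineConfig:
    """Everything the extraction pipeline needs besides the data itself."""

    green_threshold: float = GREEN_INDEX_THRESHOLD
    ndvi_threshold: float = 0.25
    stem_threshold: float = 1.2
    fluor_threshold: int = 70
    mm_per_pixel_zoom1: float = MM_PER_PIXEL_ZOOM1
    mm_per_pixel_zoom2: float = MM_PER_PIXEL_ZOOM2
    zoom_schedule: dict[int, int] = field(default_factory=dict)
    exclusions: list[tuple[int, int, int, int]] = field(default_factory=list)
    fluor_roi: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    band_count: int = 243
    wavelength_range_nm: tuple[float, float] = (546.0, 1700.0)
    smoothing_bandwidth_days: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("green_threshold", "ndvi_threshold", "stem_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fluor_threshold <= 0:
            raise ValueError("fluor_threshold must be positive")

    def require_zoom_coverage(self, days: Sequence[int]) -> None:
        """Fail fast when a supplied schedule misses an indexed day."""
        if not self.zoom_schedule:
            return
        missing = sorted(set(int(d) for d in days) - set(self.zoom_schedule))
        if missing:
            raise ValueError(f"zoom schedule missing days {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "zoom_schedule" in raw:
            raw["zoom_schedule"] = {int(k): int(v) for k, v in raw["zoom_schedule"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["wavelength_range_nm"] = list(self.wavelength_range_nm)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
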
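"""Synthetic phantom-plant experiments with exact ground truth.

This module emulates the greenhouse experiment end to end: the 10x16 pot
design, daily side/top imaging of every plant with three camera types (RGB,
fluorescence, hyperspectral), logistic growth with additive genotype / row /
error variance components, per-image illumination drift in the hyperspectral
chamber, and genotype-dependent tissue density linking final plant area to
fresh biomass.  Every rendered scene comes with its exact truth masks and
trait values, so each downstream stage (segmentation, geometry, heritability,
biomass-error decomposition) has a pixel- or value-level oracle.

Phantom geometry is deliberately simple — a vertical stem rectangle plus
horizontal elliptical leaves — so the truth bounding box is analytic: the
stem spans exactly the planted height and the widest leaf spans exactly the
planted width.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .design import ExperimentDesign, generate_design
from .hyper import HyperCube, default_wavelength_grid, write_cube
from .rgb import RasterImage

POT_MARGIN = 20       # rows reserved below the stem base for the pot
CANVAS_MARGIN = 12    # minimum clearance above the tallest phantom

# plant colors chosen so every plant pixel has green index 2G/(R+B) > 1.15
STEM_RGB = (60, 160, 50)
LEAF_RGB = (40, 180, 40)
BACKGROUND_RGB = (120, 120, 120)  # green index exactly 1.0
POT_RGB = (110, 70, 90)

FLUOR_BACKGROUND_RED = 30
FLUOR_GB = 2

# reflectance templates (piecewise linear in wavelength, nm -> reflectance).
# Leaf: classic red edge (dark at 705 nm, bright at 750 nm) and a flat NIR
# plateau, so NDVI is high and R1056/R1151 stays near 1.  Stem: red edge
# plus elevated reflectance near 1056 nm against 1151 nm, pushing the stem
# ratio well above 1.2.  Background: spectrally flat soil/backdrop.
LEAF_KNOTS = [(546, 0.10), (680, 0.08), (705, 0.12), (750, 0.47), (900, 0.50),
              (1056, 0.50), (1151, 0.47), (1250, 0.48), (1450, 0.25),
              (1550, 0.38), (1700, 0.30)]
STEM_KNOTS = [(546, 0.15), (680, 0.13), (705, 0.15), (750, 0.38), (900, 0.42),
              (1056, 0.62), (1151, 0.42), (1250, 0.44), (1450, 0.30),
              (1550, 0.36), (1700, 0.32)]
BACKGROUND_REFLECTANCE = 0.18
HYPER_INTENSITY_SCALE = 160.0  # reflectance -> 8-bit digital number


def _template(knots, wavelengths_nm: np.ndarray) -> np.ndarray:
    xs, ys = zip(*knots)
    return np.interp(wavelengths_nm, xs, ys)


def _stable_hash(s: str) -> int:
    """Process-independent small integer hash for seeding."""
    return zlib.crc32(s.encode()) % (2**31)


class ConfigError(ValueError):
    """Invalid synthetic-experiment configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the emulated experiment.

    Variances are in squared trait units (pixels^2 for the default canvas);
    ``density_by_genotype`` maps genotype id to grams of fresh biomass per
    zoom-1-adjusted pixel of summed side-view area.  ``illumination_drift_sd``
    is the log-scale sd of the per-image multiplicative lamp factor.
    """

    seed: int = 0
    n_days: int = 29
    band_count: int = 243
    wavelength_range_nm: tuple[float, float] = (546.0, 1700.0)
    canvas: tuple[int, int] = (400, 300)        # side-view rows, cols
    hyper_canvas: tuple[int, int] = (200, 150)
    genotype_variance: float = 150.0
    row_variance: float = 25.0
    error_variance: float = 50.0
    density_base: float = 0.04                  # g per adjusted pixel
    density_spread: float = 0.25                # log-scale genotype sd
    density_by_genotype: Mapping[str, float] | None = None
    biomass_noise_sd: float = 5.0               # g, additive
    illumination_drift_sd: float = 0.05
    zoom_schedule: Mapping[int, int] = field(default_factory=dict)
    emergence_day: int = 3
    max_height_px: float = 220.0                # logistic growth asymptote
    growth_rate: float = 0.35                   # logistic steepness per day
    fluor_red_range: tuple[int, int] = (150, 255)

    def __post_init__(self) -> None:
        for name in ("genotype_variance", "row_variance", "error_variance"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.band_count < 2:
            raise ConfigError("band_count must be at least 2")
        if not self.wavelength_range_nm[0] < self.wavelength_range_nm[1]:
            raise ConfigError("wavelength range must be strictly increasing")
        for z in self.zoom_schedule.values():
            if z not in (1, 2):
                raise ConfigError("zoom levels must be 1 or 2")
        if self.illumination_drift_sd < 0:
            raise ConfigError("illumination_drift_sd must be non-negative")
        lo, hi = self.fluor_red_range
        if not (70 < lo <= hi <= 255):
            raise ConfigError("fluorescence red range must lie in (70, 255]")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return default_wavelength_grid(self.band_count, self.wavelength_range_nm)

    def zoom_at(self, day: int) -> int:
        return int(self.zoom_schedule.get(day, 1))


@dataclass(frozen=True)
class PhantomTruth:
    """Exact truth for one rendered plant/day/view."""

    plant: str
    genotype: str
    day: int
    view: str
    plant_mask: np.ndarray
    stem_mask: np.ndarray
    leaf_mask: np.ndarray
    height_px: int
    width_px: int

    @property
    def area_px(self) -> int:
        return int(self.plant_mask.sum())


def _odd(x: int) -> int:
    x = int(x)
    return x if x % 2 == 1 else x + 1


def stem_width_for(height_px: int) -> int:
    return _odd(max(3, height_px // 20))


def phantom_side_masks(
    canvas: tuple[int, int], height_px: int, width_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Side-view (plant, stem) masks for planted height/width.

    The stem rectangle spans exactly ``height_px`` rows; when the phantom is
    tall enough to carry leaves, the widest leaf ellipse spans exactly
    ``width_px`` columns (``width_px`` is forced odd and at least the stem
    width by the caller).  Leaf ellipses are kept inside the stem's row span
    so the mask bounding box equals the planted extents.
    """
    rows, cols = canvas
    plant = np.zeros(canvas, dtype=bool)
    stem = np.zeros(canvas, dtype=bool)
    if height_px <= 0:
        return plant, stem
    if height_px > rows - POT_MARGIN - CANVAS_MARGIN:
        raise ValueError("phantom height exceeds canvas")
    cx = cols // 2
    base = rows - POT_MARGIN - 1
    top = base - height_px + 1
    sw = stem_width_for(height_px)
    half_sw = sw // 2
    stem[top : base + 1, cx - half_sw : cx + half_sw + 1] = True
    half_w = width_px // 2
    if height_px >= 12 and half_w > half_sw:
        if cx - half_w < 0 or cx + half_w >= cols:
            raise ValueError("phantom width exceeds canvas")
        n_leaves = min(5, max(2, height_px // 25))
        for k in range(n_leaves):
            frac = 0.25 + 0.55 * k / max(1, n_leaves - 1)
            r = int(round(base - frac * (height_px - 1)))
            r_rad = 3
            r = min(max(r, top + r_rad), base - r_rad)
            c_rad = half_w if k == 0 else max(
                half_sw + 1, int(round(half_w * (1.0 - 0.6 * k / n_leaves)))
            )
            rr, cc = ellipse(r, cx, r_rad + 0.5, c_rad + 0.5, shape=canvas)
            leaf = np.zeros(canvas, dtype=bool)
            leaf[rr, cc] = True
            plant |= leaf
    plant |= stem
    return plant, stem


def phantom_top_masks(
    canvas: tuple[int, int], height_px: int, width_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-view masks: two crossed leaf ellipses over a small stem disc."""
    rows, cols = canvas
    plant = np.zeros(canvas, dtype=bool)
    stem = np.zeros(canvas, dtype=bool)
    if height_px <= 0:
        return plant, stem
    cr, cc0 = rows // 2, cols // 2
    half_w = min(width_px // 2, rows // 2 - 2, cols // 2 - 2)
    minor = max(2, half_w // 4)
    rr, cc = ellipse(cr, cc0, minor + 0.5, max(minor, half_w) + 0.5, shape=canvas)
    plant[rr, cc] = True
    rr, cc = ellipse(cr, cc0, max(minor, half_w) + 0.5, minor + 0.5, shape=canvas)
    plant[rr, cc] = True
    half_sw = stem_width_for(height_px) // 2 + 1
    rr, cc = ellipse(cr, cc0, half_sw + 0.5, half_sw + 0.5, shape=canvas)
    stem[rr, cc] = True
    plant |= stem
    return plant, stem


# ---------------------------------------------------------------------------


def simulate_trait_panel(
    design: ExperimentDesign, config: SynthConfig, seed: int | None = None
) -> pd.DataFrame:
    """True daily trait values under the additive variance-component model.

    For each trait, plant (row i, pot j) and day t:

        y = mu_t + alpha_i + gamma_g(i,j) + eps_ijt

    with gamma drawn once per genotype (variance ``genotype_variance``),
    alpha once per greenhouse row (``row_variance``) and eps independently
    per plant-day (``error_variance``).  mu_t follows a logistic growth
    curve; days before ``emergence_day`` have y = 0 (plant not yet visible).
    Width uses the same model with effects scaled to 45% of the height
    effects.  The ``rendered`` column is the running maximum of the raw
    value per plant, the monotone envelope consumed by the image renderers.
    Same seed, same table.
    """
    if seed is None:
        seed = config.seed
    occ = design.occupied
    days = np.arange(1, config.n_days + 1)
    t0 = 0.55 * config.n_days
    mu = config.max_height_px / (1.0 + np.exp(-config.growth_rate * (days - t0)))
    frames = []
    for trait, scale in (("height", 1.0), ("width", 0.45)):
        rng = np.random.default_rng([seed, _stable_hash(trait)])
        gamma = {
            g: rng.normal(0.0, np.sqrt(config.genotype_variance)) * scale
            for g in sorted(occ["genotype"].unique())
        }
        alpha = rng.normal(0.0, np.sqrt(config.row_variance), size=10) * scale
        eps = rng.normal(
            0.0, np.sqrt(config.error_variance), size=(len(occ), len(days))
        ) * scale
        base = np.maximum(mu * scale, 0.0)
        for p, rec in enumerate(occ.itertuples()):
            y = base + alpha[rec.row - 1] + gamma[rec.genotype] + eps[p]
            y[days < config.emergence_day] = 0.0
            rendered = np.maximum.accumulate(np.clip(y, 0.0, None))
            frames.append(
                pd.DataFrame(
                    {
                        "plant": rec.plant,
                        "genotype": rec.genotype,
                        "row": rec.row,
                        "col": rec.col,
                        "replicate": rec.replicate,
                        "day": days,
                        "trait": trait,
                        "value": y,
                        "rendered": rendered,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


class SyntheticExperiment:
    """A seeded synthetic experiment: design + trait panel + renderers."""

    def __init__(self, design: ExperimentDesign | None = None,
                 config: SynthConfig | None = None):
        self.config = config or SynthConfig()
        self.design = design if design is not None else generate_design(self.config.seed)
        self.panel = simulate_trait_panel(self.design, self.config)
        wide = self.panel.pivot_table(
            index=["plant", "genotype", "row", "col", "replicate", "day"],
            columns="trait",
            values="rendered",
        ).reset_index()
        self._rendered = {
            (r.plant, int(r.day)): (float(r.height), float(r.width))
            for r in wide.itertuples()
        }
        self._byplant = self.design.occupied.set_index("plant")
        self._allpots = self.design.table.set_index("plant")

    # -- geometry ----------------------------------------------------------

    @property
    def plants(self) -> list[str]:
        """Plant ids of the 156 occupied pots."""
        return list(self._byplant.index)

    def _planted_dims(self, plant: str, day: int,
                      canvas: tuple[int, int]) -> tuple[int, int]:
        """Integer (height, width) drawn on ``canvas``; (0, 0) for empty pots."""
        if plant not in self._allpots.index:
            raise KeyError(f"unknown pot: {plant}")
        if not 1 <= day <= self.config.n_days:
            raise ValueError(f"day {day} outside 1..{self.config.n_days}")
        if plant not in self._byplant.index:  # empty control pot
            return 0, 0
        h_raw, w_raw = self._rendered[(plant, day)]
        scale = canvas[0] / self.config.canvas[0]
        h = int(round(h_raw * scale))
        if h <= 0:
            return 0, 0
        h = min(h, canvas[0] - POT_MARGIN - CANVAS_MARGIN)
        sw = stem_width_for(h)
        w = _odd(max(int(round(w_raw * scale)), sw))
        w = min(w, _odd(canvas[1] - 8))
        if h < 12 or w <= sw:
            w = sw
        return h, w

    def _truth(self, plant: str, day: int, view: str,
               canvas: tuple[int, int]) -> PhantomTruth:
        rec = self._allpots.loc[plant]
        h, w = self._planted_dims(plant, day, canvas)
        maker = phantom_top_masks if view == "top" else phantom_side_masks
        plant_mask, stem_mask = maker(canvas, h, w)
        if view == "top" and h > 0:
            rows, cols = np.nonzero(plant_mask)
            h = int(rows.max() - rows.min() + 1)
            w = int(cols.max() - cols.min() + 1)
        return PhantomTruth(
            plant=plant,
            genotype=rec["genotype"],
            day=day,
            view=view,
            plant_mask=plant_mask,
            stem_mask=stem_mask,
            leaf_mask=plant_mask & ~stem_mask,
            height_px=h,
            width_px=w,
        )

    # -- renderers ---------------------------------------------------------

    def render_rgb(self, plant: str, day: int, view: str = "side0"
                   ) -> tuple[RasterImage, PhantomTruth]:
        """RGB scene: gray backdrop, pot, green phantom; truth attached."""
        truth = self._truth(plant, day, view, self.config.canvas)
        rows, cols = self.config.canvas
        img = np.empty((rows, cols, 3), dtype=np.uint8)
        img[...] = BACKGROUND_RGB
        if view != "top":
            img[rows - POT_MARGIN :, cols // 2 - 25 : cols // 2 + 25] = POT_RGB
        img[truth.leaf_mask] = LEAF_RGB
        img[truth.stem_mask] = STEM_RGB
        return (
            RasterImage(img, view=view, day=day, zoom=self.config.zoom_at(day)),
            truth,
        )

    def render_hypercube(self, plant: str, day: int, view: str = "side0"
                         ) -> tuple[HyperCube, PhantomTruth]:
        """Hyperspectral cube with template spectra and illumination drift.

        Every pixel carries its tissue's reflectance template scaled to
        8-bit digital numbers; the whole image is multiplied by one
        lognormal lamp factor drawn per (plant, day) from the seed.  Band
        ratios (NDVI, stem ratio) are invariant to that global factor.
        """
        cfg = self.config
        truth = self._truth(plant, day, view, cfg.hyper_canvas)
        wl = cfg.wavelengths_nm
        leaf_spec = _template(LEAF_KNOTS, wl) * HYPER_INTENSITY_SCALE
        stem_spec = _template(STEM_KNOTS, wl) * HYPER_INTENSITY_SCALE
        bg = BACKGROUND_REFLECTANCE * HYPER_INTENSITY_SCALE
        if cfg.illumination_drift_sd > 0:
            rng = np.random.default_rng(
                [cfg.seed, 7, _stable_hash(plant), day]
            )
            lamp = float(np.exp(rng.normal(0.0, cfg.illumination_drift_sd)))
        else:
            lamp = 1.0
        planes = np.full((cfg.band_count, *cfg.hyper_canvas), bg)
        planes[:, truth.leaf_mask] = leaf_spec[:, None]
        planes[:, truth.stem_mask] = stem_spec[:, None]
        planes = np.clip(np.round(planes * lamp), 0, 255).astype(np.uint8)
        return HyperCube(planes, wl), truth

    def render_fluorescence(self, plant: str, day: int, view: str = "side0"
                            ) -> tuple[RasterImage, PhantomTruth]:
        """Fluorescence frame: red-channel signal on plant pixels only."""
        cfg = self.config
        truth = self._truth(plant, day, view, cfg.canvas)
        img = np.zeros((*cfg.canvas, 3), dtype=np.uint8)
        img[..., 0] = FLUOR_BACKGROUND_RED
        img[..., 1:] = FLUOR_GB
        lo, hi = cfg.fluor_red_range
        rng = np.random.default_rng(
            [cfg.seed, 11, _stable_hash(plant), day, _stable_hash(view)]
        )
        n = truth.area_px
        if n:
            img[..., 0][truth.plant_mask] = rng.integers(lo, hi + 1, size=n)
        return (
            RasterImage(img, view=view, day=day, zoom=self.config.zoom_at(day)),
            truth,
        )

    # -- biomass truth -----------------------------------------------------

    def densities(self) -> dict[str, float]:
        """Per-genotype tissue density (g per adjusted pixel)."""
        if self.config.density_by_genotype is not None:
            return dict(self.config.density_by_genotype)
        rng = np.random.default_rng([self.config.seed, 13])
        out = {}
        for g in sorted(self._byplant["genotype"].unique()):
            out[g] = self.config.density_base * float(
                np.exp(rng.normal(0.0, self.config.density_spread))
            )
        return out

    def final_day_truth(self) -> pd.DataFrame:
        """Final-day side-view truth areas per plant (both side views)."""
        day = self.config.n_days
        zoom = self.config.zoom_at(day)
        scale = {1: 1.0, 2: 1.507 / 0.746}[zoom]
        rows = []
        for plant in self._byplant.index:
            area = sum(
                self._truth(plant, day, v, self.config.canvas).area_px
                for v in ("side0", "side90")
            )
            rec = self._byplant.loc[plant]
            rows.append(
                {
                    "plant": plant,
                    "genotype": rec["genotype"],
                    "row": rec["row"],
                    "replicate": rec["replicate"],
                    "day": day,
                    "side_area_px": area,
                    "side_area_adj": area * scale**2,
                }
            )
        return pd.DataFrame(rows)

    def simulate_biomass_truth(self, truth: pd.DataFrame | None = None
                               ) -> pd.DataFrame:
        """Fresh biomass per plant from genotype density x adjusted area.

        biomass_g = density[genotype] * side_area_adj + N(0, noise_sd).
        The genotype-dependent density is what makes any density-blind
        pixel-count predictor systematically wrong per genotype.
        """
        if truth is None:
            truth = self.final_day_truth()
        dens = self.densities()
        missing = set(truth["genotype"]) - set(dens)
        if missing:
            raise ConfigError(f"no density configured for genotypes {sorted(missing)}")
        rng = np.random.default_rng([self.config.seed, 17])
        out = truth.copy()
        noise = (
            rng.normal(0.0, self.config.biomass_noise_sd, size=len(out))
            if self.config.biomass_noise_sd > 0
            else np.zeros(len(out))
        )
        out["fresh_biomass_g"] = (
            out["genotype"].map(dens).to_numpy() * out["side_area_adj"].to_numpy()
            + noise
        )
        return out


# ---------------------------------------------------------------------------
# spec-level convenience wrappers


def render_rgb_scene(design, plant, day, view, config):
    return SyntheticExperiment(design, config).render_rgb(plant, day, view)


def render_hypercube(design, plant, day, config, view="side0"):
    return SyntheticExperiment(design, config).render_hypercube(plant, day, view)


def render_fluorescence_image(design, plant, day, config, view="side0"):
    return SyntheticExperiment(design, config).render_fluorescence(plant, day, view)


def simulate_biomass_truth(experiment: SyntheticExperiment,
                           truth: pd.DataFrame | None = None) -> pd.DataFrame:
    return experiment.simulate_biomass_truth(truth)


# ---------------------------------------------------------------------------
# dataset writer (released-layout emulation)


def _genotype_dir(genotype: str) -> str:
    return f"Genotype_ZL{int(genotype[2:]):03d}"


def simulate_dataset(
    out_dir,
    config: SynthConfig | None = None,
    design: ExperimentDesign | None = None,
    plants: Sequence[str] | None = None,
    days: Sequence[int] | None = None,
    cameras: Sequence[str] = ("RGB", "Fluorescence", "Hyperspectral"),
) -> SyntheticExperiment:
    """Write a synthetic experiment in the released dataset layout.

    Layout: ``Genotype_ZLxxx/Plant_<id>/<Camera>/Day_NN/...`` with the
    hyperspectral day folder nested one level deeper per wavelength.  Also
    writes ``design.csv`` and the truth tables under ``truth/``.  ``plants``
    and ``days`` subset the (large) full experiment; hyperspectral cubes are
    written for the side0 view only.
    """
    exp = SyntheticExperiment(design, config)
    cfg = exp.config
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    exp.design.to_csv(root / "design.csv")
    if plants is None:
        plants = list(exp._byplant.index)
    if days is None:
        days = list(range(1, cfg.n_days + 1))
    truth_rows = []
    for plant in plants:
        geno = exp._byplant.loc[plant, "genotype"]
        pdir = root / _genotype_dir(geno) / f"Plant_{plant}"
        for day in days:
            for view in ("side0", "side90", "top"):
                if "RGB" in cameras:
                    img, truth = exp.render_rgb(plant, day, view)
                    d = pdir / "RGB" / f"Day_{day:02d}"
                    d.mkdir(parents=True, exist_ok=True)
                    iio.imwrite(d / f"{view}.png", img.pixels)
                    truth_rows.append(
                        {
                            "plant": plant,
                            "genotype": geno,
                            "day": day,
                            "view": view,
                            "height_px": truth.height_px,
                            "width_px": truth.width_px,
                            "area_px": truth.area_px,
                        }
                    )
                if "Fluorescence" in cameras:
                    img, _ = exp.render_fluorescence(plant, day, view)
                    d = pdir / "Fluorescence" / f"Day_{day:02d}"
                    d.mkdir(parents=True, exist_ok=True)
                    iio.imwrite(d / f"{view}.png", img.pixels)
            if "Hyperspectral" in cameras:
                cube, _ = exp.render_hypercube(plant, day, "side0")
                write_cube(cube, pdir / "Hyperspectral" / f"Day_{day:02d}")
    truth_dir = root / "truth"
    truth_dir.mkdir(exist_ok=True)
    pd.DataFrame(truth_rows).to_csv(truth_dir / "traits_truth.csv", index=False)
    exp.simulate_biomass_truth().to_csv(truth_dir / "biomass.csv", index=False)
    # pot-weight stub: the real platform logs watering data; not simulated
    pd.DataFrame(columns=["plant", "day", "weight_g"]).to_csv(
        truth_dir / "pot_weights.csv", index=False
    )
    return exp
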
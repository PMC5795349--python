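"""End-to-end pipeline: index -> extract -> heritability -> biomass.

Each stage reads the outputs of the previous one and writes plain CSV/PNG
artifacts plus a MANIFEST.json recording per-stage status and counts, so a
partially failed run leaves an auditable trail.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from . import biomass as biomass_mod
from . import fluor as fluor_mod
from . import hyper as hyper_mod
from . import quantgen
from . import rgb as rgb_mod
from .config import PipelineConfig
from .dataset import index_dataset

log = logging.getLogger(__name__)

# trait naming of the field: P{H,W,A}{0,90} per view, PF for fluorescence
_VIEW_SUFFIX = {"side0": "0", "side90": "90"}


def _calib(config: PipelineConfig) -> rgb_mod.ZoomCalibration:
    return rgb_mod.ZoomCalibration(
        config.mm_per_pixel_zoom1, config.mm_per_pixel_zoom2, config.zoom_schedule
    )


def extract_rgb(index: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    return rgb_mod.build_trait_timeseries(
        index, _calib(config), config.green_threshold, config.exclusions
    )


def extract_fluor(index: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    recs = index[index["camera"] == "Fluorescence"]
    rows = []
    calib = _calib(config)
    for rec in recs.itertuples():
        img = iio.imread(rec.path)
        roi = config.fluor_roi.get(calib.zoom_at(rec.day))
        mask = fluor_mod.segment_fluorescence(img, roi, config.fluor_threshold)
        res = fluor_mod.fluorescence_intensity(mask, img)
        rows.append(
            {
                "plant": rec.plant,
                "genotype": rec.genotype,
                "day": rec.day,
                "view": rec.view,
                "aggregate_intensity": res.aggregate_intensity,
                "mean_intensity": res.mean_intensity,
                "n_pixels": res.n_pixels,
            }
        )
    return pd.DataFrame(rows)


def extract_hyper(
    index: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Path | None = None,
    false_color: bool = True,
    pca_on_normalized: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per plant/day stem-leaf pixel counts and tissue mean spectra.

    Cubes are NDVI-masked, stem/leaf split, background-normalized; when
    ``false_color`` is set a pooled pixel-PCA false-color PNG per cube is
    written under ``out_dir``/falsecolor (fitted on normalized intensities
    unless ``pca_on_normalized`` is off).
    """
    recs = index[index["camera"] == "Hyperspectral"]
    counts, spectra = [], []
    cubes, masks, keys = [], [], []
    for (plant, geno, day), grp in recs.groupby(["plant", "genotype", "day"]):
        day_dir = Path(grp["path"].iloc[0]).parent.parent
        cube = hyper_mod.read_cube(day_dir)
        pmask = hyper_mod.segment_plant_ndvi(cube, config.ndvi_threshold)
        stem, leaf = hyper_mod.segment_stem(cube, pmask, config.stem_threshold)
        counts.append(
            {
                "plant": plant,
                "genotype": geno,
                "day": day,
                "plant_pixels": pmask.n_pixels,
                "stem_pixels": stem.n_pixels,
                "leaf_pixels": leaf.n_pixels,
            }
        )
        if pmask.is_na:
            continue
        norm = hyper_mod.normalize_cube(cube, pmask)
        for tissue, m in (("plant", pmask), ("stem", stem), ("leaf", leaf)):
            if m.is_na:
                continue
            summ = hyper_mod.mean_spectrum(norm, m, tissue)
            spectra.extend(
                {
                    "plant": plant,
                    "day": day,
                    "tissue": tissue,
                    "wavelength_nm": wl,
                    "mean_intensity": v,
                    "n_pixels": summ.n_pixels,
                }
                for wl, v in zip(summ.wavelengths_nm, summ.mean_intensity)
            )
        cubes.append(norm if pca_on_normalized else cube)
        masks.append(pmask)
        keys.append((plant, day))
    if false_color and out_dir is not None and cubes:
        fc_dir = Path(out_dir) / "falsecolor"
        fc_dir.mkdir(parents=True, exist_ok=True)
        images, _ = hyper_mod.pca_false_color(cubes, masks)
        for (plant, day), img in zip(keys, images):
            iio.imwrite(fc_dir / f"{plant}_day{day:02d}.png", img)
    return pd.DataFrame(counts), pd.DataFrame(spectra)


def heritability_table(
    traits: pd.DataFrame, design: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Per-day adjusted/classical HR for each trait x side view.

    ``design`` maps plant -> row/replicate; traits from the top view are
    left out (the published analysis uses the two side views).  The
    smoothed column applies the Gaussian local-mean smoother over days.
    """
    meta = design.set_index("plant")[["row", "replicate"]]
    out = []
    for (trait, view), d in traits.groupby(["trait", "view"]):
        if view not in _VIEW_SUFFIX or trait not in (
            "height_px", "width_px", "area_adj"
        ):
            continue
        d = d.join(meta, on="plant")
        series = quantgen.heritability_series(d)
        if series.empty:
            continue
        label = {"height_px": "PH", "width_px": "PW", "area_adj": "PA"}[trait]
        series.insert(0, "trait", f"{label}{_VIEW_SUFFIX[view]}")
        if len(series) >= 3:
            series["hr_adjusted_smooth"] = quantgen.smooth_heritability(
                series["day"].to_numpy(),
                series["hr_adjusted"].to_numpy(),
                config.smoothing_bandwidth_days,
            )
        out.append(series)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def run_pipeline(root, out, config: PipelineConfig | None = None) -> int:
    """Run every stage over a dataset tree; return a process exit status.

    Writes traits.csv, fluor.csv, hyper_counts.csv, spectra.csv, h2.csv,
    biomass.json and falsecolor PNGs under ``out``; MANIFEST.json records
    which stages completed.  A stage exception stops the run, leaves the
    artifacts produced so far, and yields a nonzero status.
    """
    config = config or PipelineConfig()
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    status = 0
    try:
        index = index_dataset(root)
        config.require_zoom_coverage(index[index["camera"] == "RGB"]["day"].unique())
        manifest["index"] = {"status": "ok", "records": len(index)}

        traits = extract_rgb(index, config)
        traits.to_csv(out / "traits.csv", index=False, na_rep="")
        manifest["rgb"] = {"status": "ok", "rows": len(traits)}

        fl = extract_fluor(index, config)
        fl.to_csv(out / "fluor.csv", index=False, na_rep="")
        manifest["fluor"] = {"status": "ok", "rows": len(fl)}

        counts, spectra = extract_hyper(index, config, out)
        counts.to_csv(out / "hyper_counts.csv", index=False, na_rep="")
        spectra.to_csv(out / "spectra.csv", index=False, na_rep="")
        manifest["hyper"] = {"status": "ok", "cubes": len(counts)}

        design_csv = Path(root) / "design.csv"
        if design_csv.exists():
            design = pd.read_csv(design_csv)
            h2 = heritability_table(traits, design, config)
            h2.to_csv(out / "h2.csv", index=False, na_rep="")
            manifest["heritability"] = {"status": "ok", "rows": len(h2)}
        else:
            design = None
            manifest["heritability"] = {"status": "skipped", "reason": "no design.csv"}

        biomass_csv = Path(root) / "truth" / "biomass.csv"
        if design is not None and biomass_csv.exists():
            bm = pd.read_csv(biomass_csv)
            features = biomass_mod.assemble_features(traits, fl, counts, bm)
            results = {}
            for method in ("univariate_linear", "multivariate_linear"):
                try:
                    res = biomass_mod.fit_biomass(features, method, seed=config.seed)
                    results[method] = {
                        "r": res.r,
                        "genotype_error_fraction": biomass_mod.genotype_error_fraction(
                            res, features
                        ),
                    }
                except ValueError as exc:
                    results[method] = {"error": str(exc)}
            (out / "biomass.json").write_text(json.dumps(results, indent=2))
            manifest["biomass"] = {"status": "ok", "methods": sorted(results)}
        else:
            manifest["biomass"] = {"status": "skipped", "reason": "no ground truth"}
    except Exception as exc:  # stage failure: keep partial outputs
        log.exception("pipeline stage failed")
        manifest["failure"] = {"status": "error", "message": str(exc)}
        status = 1
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return status
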
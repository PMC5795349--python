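"""Walking the released dataset layout into a flat index.

The on-disk hierarchy is ``Genotype_ZLxxx/Plant_<pot>-<genotype>/<Camera>/
Day_NN/...``; RGB and fluorescence days hold one PNG per view, while
hyperspectral days add one more nesting level, a folder per wavelength
(integer nm) holding the single-band grayscale image.  Thermal IR folders
are indexed but carry no processing here.  Real deposits differ slightly in
file naming, so the per-file parsing is pluggable.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

KNOWN_CAMERAS = ("RGB", "Fluorescence", "Hyperspectral", "IR")

_GENO_RE = re.compile(r"Genotype_ZL0*(\d+)$")
_PLANT_RE = re.compile(r"Plant_(.+)$")
_DAY_RE = re.compile(r"Day_0*(\d+)$")


def default_view_parser(path: Path) -> str | None:
    """View label from an image filename ('side0.png' -> 'side0')."""
    stem = path.stem
    return stem if stem in ("side0", "side90", "top") else None


def index_dataset(root, view_parser=default_view_parser) -> pd.DataFrame:
    """Index every image under ``root``.

    Returns a DataFrame with columns genotype, plant, camera, day, view,
    wavelength_nm (hyperspectral only) and path.  Unknown camera-type
    directories and extraneous files are logged and skipped.  An empty or
    missing root is an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[dict] = []
    for gdir in sorted(root.iterdir()):
        m = _GENO_RE.match(gdir.name) if gdir.is_dir() else None
        if not m:
            continue
        genotype = f"ZL{int(m.group(1))}"
        for pdir in sorted(gdir.iterdir()):
            pm = _PLANT_RE.match(pdir.name) if pdir.is_dir() else None
            if not pm:
                log.warning("skipping unexpected entry %s", pdir)
                continue
            plant = pm.group(1)
            for cdir in sorted(pdir.iterdir()):
                if not cdir.is_dir():
                    log.warning("skipping unexpected file %s", cdir)
                    continue
                if cdir.name not in KNOWN_CAMERAS:
                    log.warning("skipping unknown camera type %s", cdir)
                    continue
                for ddir in sorted(cdir.iterdir()):
                    dm = _DAY_RE.match(ddir.name) if ddir.is_dir() else None
                    if not dm:
                        continue
                    day = int(dm.group(1))
                    base = {
                        "genotype": genotype,
                        "plant": plant,
                        "camera": cdir.name,
                        "day": day,
                    }
                    if cdir.name == "Hyperspectral":
                        for wdir in sorted(ddir.iterdir()):
                            if not (wdir.is_dir() and wdir.name.isdigit()):
                                continue
                            for f in sorted(wdir.glob("*.png")):
                                records.append(
                                    base
                                    | {
                                        "view": "side0",
                                        "wavelength_nm": float(wdir.name),
                                        "path": str(f),
                                    }
                                )
                    else:
                        for f in sorted(ddir.glob("*.png")):
                            view = view_parser(f)
                            if view is None:
                                log.warning("skipping unrecognized image %s", f)
                                continue
                            records.append(
                                base
                                | {
                                    "view": view,
                                    "wavelength_nm": float("nan"),
                                    "path": str(f),
                                }
                            )
    if not records:
        raise ValueError(f"no images found under {root}")
    idx = pd.DataFrame(records)
    log.info(
        "indexed %d records: %d plants, cameras %s",
        len(idx),
        idx["plant"].nunique(),
        dict(idx.groupby("camera").size()),
    )
    return idx
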
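"""Readers and writers for the pipeline's on-disk artifacts.

Formats are deliberately plain: ground-truth fields and region lists are
CSV, irradiation plans and reports are JSON, and tiles are multi-channel
TIFFs with a JSON sidecar carrying stage offset and pixel size.  Every
writer/reader pair round-trips losslessly (floats are serialised with full
repr precision) and writes deterministically, so a fixed-seed run produces
a byte-identical artifact tree.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import LaserSettings, PipelineConfig
from .detect import REGION_COLUMNS
from .field import CELL_COLUMNS, ImageTile, PollenField
from .plan import SHOT_COLUMNS, IrradiationPlan

__all__ = [
    "write_field_csv",
    "read_field_csv",
    "write_regions_csv",
    "read_regions_csv",
    "write_plan_json",
    "read_plan_json",
    "write_tiles",
    "read_tiles",
    "load_pipeline_config",
]

_FIELD_CSV_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "diameter_um",
    "class",
    "fda_on",
    "red_on",
    "displaced",
    "shrunken",
    "green_level",
]


def write_field_csv(field: PollenField, path: str | Path) -> None:
    path = Path(path)
    df = field.cells[CELL_COLUMNS].rename(columns={"cls": "class"})
    with open(path, "w") as fh:
        fh.write(f"# area_width_um={field.width_um!r}\n")
        fh.write(f"# area_height_um={field.height_um!r}\n")
        df.to_csv(fh, index=False, columns=_FIELD_CSV_COLUMNS)


def read_field_csv(path: str | Path) -> PollenField:
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    df = pd.read_csv(path, comment="#").rename(columns={"class": "cls"})
    for col in ("fda_on", "red_on", "displaced", "shrunken"):
        df[col] = df[col].astype(bool)
    return PollenField(df, meta["area_width_um"], meta["area_height_um"])


def write_regions_csv(regions: pd.DataFrame, path: str | Path) -> None:
    regions[REGION_COLUMNS].to_csv(path, index=False)


def read_regions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        df = df.astype(
            {
                "region_id": int,
                "tile_id": int,
                "is_viable": bool,
                "is_target": bool,
                "is_clump": bool,
            },
            errors="ignore",
        )
    else:
        for col in ("is_viable", "is_target", "is_clump"):
            df[col] = df[col].astype(bool)
    return df[REGION_COLUMNS]


def write_plan_json(plan: IrradiationPlan, path: str | Path) -> None:
    doc = {
        "laser": plan.laser.model_dump(),
        "shots": [
            {
                "region_id": int(s.region_id),
                "tile_id": int(s.tile_id),
                "x_um": float(s.x_um),
                "y_um": float(s.y_um),
            }
            for s in plan.shots.itertuples()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_plan_json(path: str | Path) -> IrradiationPlan:
    doc = json.loads(Path(path).read_text())
    laser = LaserSettings(**doc["laser"])
    shots = pd.DataFrame(doc["shots"], columns=SHOT_COLUMNS)
    shots = shots.astype({"region_id": int, "tile_id": int, "x_um": float, "y_um": float})
    return IrradiationPlan(laser, shots)


def write_tiles(tiles: list[ImageTile], out_dir: str | Path) -> list[Path]:
    """One multi-channel TIFF per tile plus a JSON sidecar with stage metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tiles:
        stem = f"tile_r{t.row:03d}_c{t.col:03d}"
        arr = np.stack([t.channels[ch] for ch in sorted(t.channels)])
        tif = out_dir / f"{stem}.tif"
        tifffile.imwrite(tif, arr, photometric="minisblack")
        sidecar = {
            "tile_id": t.tile_id,
            "row": t.row,
            "col": t.col,
            "x0_um": t.x0_um,
            "y0_um": t.y0_um,
            "pixel_size_um": t.pixel_size_um,
            "channels": sorted(t.channels),
        }
        (out_dir / f"{stem}.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
        )
        paths.append(tif)
    return paths


def read_tiles(tile_dir: str | Path) -> list[ImageTile]:
    tile_dir = Path(tile_dir)
    tiles = []
    for tif in sorted(tile_dir.glob("tile_*.tif")):
        meta = json.loads(tif.with_suffix(".json").read_text())
        arr = tifffile.imread(tif)
        channels = {ch: arr[i] for i, ch in enumerate(meta["channels"])}
        tiles.append(
            ImageTile(
                meta["tile_id"],
                meta["row"],
                meta["col"],
                meta["x0_um"],
                meta["y0_um"],
                meta["pixel_size_um"],
                channels,
            )
        )
    tiles.sort(key=lambda t: t.tile_id)
    return tiles


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a JSON or YAML document."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return PipelineConfig(**doc)
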
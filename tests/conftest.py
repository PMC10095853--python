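"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pollenbeam import (
    DetectionParams,
    FieldConfig,
    ImagingConfig,
    PollenField,
    TileGrid,
)
from pollenbeam.field import CELL_COLUMNS


@pytest.fixture
def imaging_small() -> ImagingConfig:
    """1 um/px, 500 px tiles: cheap but keeps a grain ~30 px across."""
    return ImagingConfig(pixel_size_um=1.0, tile_width_px=500, tile_height_px=500)


@pytest.fixture
def imaging_noise_free() -> ImagingConfig:
    return ImagingConfig(
        pixel_size_um=1.0,
        tile_width_px=500,
        tile_height_px=500,
        noise_sd={"green": 0.0, "red": 0.0, "brightfield": 0.0},
    )


def small_field_config(**overrides) -> FieldConfig:
    """1 mm^2 field with the reference statistics unless overridden."""
    kw = dict(
        area_width_um=1000.0,
        area_height_um=1000.0,
        density_per_mm2=84.8,
        viability_fraction=0.77,
        target_fraction_of_viable=0.058,
        dust_per_mm2=0.0,
        rng_seed=0,
    )
    kw.update(overrides)
    return FieldConfig(**kw)


def manual_field(
    cells: list[dict], width_um: float = 500.0, height_um: float = 500.0
) -> PollenField:
    """Build a field from explicit cell dicts (defaults filled in)."""
    rows = []
    for i, c in enumerate(cells):
        row = dict(
            id=i,
            diameter_um=25.0,
            cls="viable-nontarget",
            fda_on=True,
            red_on=False,
            displaced=False,
            shrunken=False,
            green_level=20000.0,
        )
        row.update(c)
        rows.append(row)
    df = pd.DataFrame(rows, columns=CELL_COLUMNS)
    cfg = FieldConfig(area_width_um=width_um, area_height_um=height_um)
    return PollenField(df, width_um, height_um, cfg)


def flood_fill_components(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Brute-force flood-fill labelling oracle (stack-based, O(npix))."""
    labels = np.zeros(mask.shape, dtype=int)
    if connectivity == 2:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    current = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels


def truth_regions(field: PollenField, grid: TileGrid | None = None) -> pd.DataFrame:
    """Region table taken straight from ground truth (planner-side oracle)."""
    df = field.pollen
    tile_id = (
        grid.tile_of(df["x_um"].to_numpy(), df["y_um"].to_numpy())
        if grid is not None
        else np.zeros(len(df), dtype=int)
    )
    return pd.DataFrame(
        {
            "region_id": df["id"].to_numpy(),
            "tile_id": tile_id,
            "x_um": df["x_um"].to_numpy(float),
            "y_um": df["y_um"].to_numpy(float),
            "diameter_um": df["diameter_um"].to_numpy(float),
            "area_px": (np.pi * (df["diameter_um"].to_numpy(float) / 2) ** 2).astype(int),
            "mean_green": df["green_level"].to_numpy(float),
            "mean_red": 0.0,
            "max_red": np.where(df["red_on"], 65535.0, 0.0),
            "is_viable": df["fda_on"].to_numpy(bool),
            "is_target": df["red_on"].to_numpy(bool),
            "is_clump": False,
        }
    )


@pytest.fixture
def detection_params() -> DetectionParams:
    return DetectionParams()
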
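"""Region detection: viable (FDA-positive) pollen, targets, dust and clumps.

The detector mirrors the automated acquisition loop: threshold a channel,
label connected components, discard components with equivalent diameter
<= 12 um (dust), and record each remaining region's stage-coordinate
centroid and channel intensities — the region list that drives irradiation
planning.  Viability is a mean-intensity criterion on the green (FDA)
channel (strictly above 9,600 counts by default); targets are recognised by
the presence of saturated red pixels, because the nuclear tdTomato signal is
far brighter than its region but smaller than the grain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label, regionprops_table

from .config import DetectionParams
from .field import ImageTile
from .rng import substream

__all__ = [
    "REGION_COLUMNS",
    "detect_regions",
    "detect_viable",
    "detect_all",
    "detect_targets",
    "flag_clumps",
    "calibrate_threshold",
    "combine_regions",
]

REGION_COLUMNS = [
    "region_id",
    "tile_id",
    "x_um",
    "y_um",
    "diameter_um",
    "area_px",
    "mean_green",
    "mean_red",
    "max_red",
    "is_viable",
    "is_target",
    "is_clump",
]


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": pd.Series(dtype=int),
            "tile_id": pd.Series(dtype=int),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "diameter_um": pd.Series(dtype=float),
            "area_px": pd.Series(dtype=int),
            "mean_green": pd.Series(dtype=float),
            "mean_red": pd.Series(dtype=float),
            "max_red": pd.Series(dtype=float),
            "is_viable": pd.Series(dtype=bool),
            "is_target": pd.Series(dtype=bool),
            "is_clump": pd.Series(dtype=bool),
        }
    )


def _check_tile(tile: ImageTile) -> None:
    if tile.pixel_size_um is None or not tile.pixel_size_um > 0:
        raise ValueError(
            f"tile {tile.tile_id}: missing or invalid pixel-size metadata; "
            "stage coordinates would be meaningless"
        )


def detect_regions(
    tile: ImageTile, params: DetectionParams, channel: str, threshold: float
) -> pd.DataFrame:
    """Threshold ``channel`` strictly above ``threshold`` and extract regions.

    Connected components (8-connectivity by default) with equivalent
    diameter strictly greater than ``params.min_diameter_um`` are emitted
    with centroids converted to stage micrometres.
    """
    _check_tile(tile)
    if channel not in tile.channels:
        raise ValueError(f"tile {tile.tile_id} has no '{channel}' channel")
    px = tile.pixel_size_um
    mask = tile.channels[channel].astype(np.float64) > threshold
    labels = _sk_label(mask, connectivity=params.connectivity)
    if labels.max() == 0:
        return _empty_regions()
    green = tile.channels.get("green")
    red = tile.channels.get("red")
    stack = np.stack(
        [
            (green if green is not None else np.zeros_like(labels)),
            (red if red is not None else np.zeros_like(labels)),
        ],
        axis=-1,
    ).astype(np.float64)
    props = regionprops_table(
        labels,
        intensity_image=stack,
        properties=("label", "area", "centroid", "intensity_mean", "intensity_max"),
    )
    area = props["area"].astype(float)
    diam_um = 2.0 * np.sqrt(area / np.pi) * px
    df = pd.DataFrame(
        {
            "region_id": props["label"].astype(int),
            "tile_id": tile.tile_id,
            "x_um": tile.x0_um + (props["centroid-1"] + 0.5) * px,
            "y_um": tile.y0_um + (props["centroid-0"] + 0.5) * px,
            "diameter_um": diam_um,
            "area_px": area.astype(int),
            "mean_green": props["intensity_mean-0"],
            "mean_red": props["intensity_mean-1"],
            "max_red": props["intensity_max-1"],
            "is_viable": False,
            "is_target": False,
            "is_clump": False,
        }
    )
    df = df[df["diameter_um"] > params.min_diameter_um].reset_index(drop=True)
    return df


def detect_viable(tile: ImageTile, params: DetectionParams) -> pd.DataFrame:
    """Detect FDA-positive pollen on the green channel (strict > threshold)."""
    df = detect_regions(tile, params, "green", params.fda_threshold)
    df["is_viable"] = True
    return df


def detect_all(tile: ImageTile, params: DetectionParams) -> pd.DataFrame:
    """Detect every grain on the brightfield channel and flag viability/targets.

    Total pollen counts (viable + non-viable) come from grain shape, exactly
    as the bookkeeping of a real run counts FDA-negative grains it will not
    irradiate.  Viability is then the per-region mean-green criterion and
    target status the saturated-red criterion.
    """
    df = detect_regions(tile, params, "brightfield", params.brightfield_threshold)
    df["is_viable"] = df["mean_green"] > params.fda_threshold
    df["is_target"] = df["max_red"] >= params.target_threshold
    return df


def detect_targets(
    regions: pd.DataFrame, tile: ImageTile, params: DetectionParams
) -> pd.DataFrame:
    """Flag regions whose red channel contains saturated pixels as targets.

    Works from the per-region red maxima recorded at detection time; all
    other flags are left untouched.
    """
    if not (regions["tile_id"] == tile.tile_id).all():
        raise ValueError("regions do not belong to the given tile")
    out = regions.copy()
    out["is_target"] = out["max_red"] >= params.target_threshold
    return out


def flag_clumps(
    regions: pd.DataFrame, params: DetectionParams
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag merged-grain regions and score per-tile pollen separation.

    A region is a clump when its pixel area exceeds
    ``clump_area_factor x median region area`` of the sample (the median is a
    robust stand-in for the single-grain area as long as clumps are a
    minority).  A tile is "separated" iff it contains no clump.
    """
    out = regions.copy()
    if len(out) == 0:
        return out, pd.Series(dtype=bool, name="separated")
    median_area = float(out["area_px"].median())
    out["is_clump"] = out["area_px"] > params.clump_area_factor * median_area
    separated = ~out.groupby("tile_id")["is_clump"].any()
    separated.name = "separated"
    return out, separated


def calibrate_threshold(
    tiles: list[ImageTile],
    n_dim: int = 10,
    seed: int = 0,
    params: DetectionParams | None = None,
) -> float:
    """Set the FDA threshold from dim grains, as the acquisition loop does.

    Candidate grains are detected on the brightfield channel; the near-
    non-fluorescent ones (green mean below an Otsu split of the candidate
    intensities, or all candidates when the sample is unimodal) are the dim
    pool.  ``n_dim`` of them are chosen at random and the mean of their mean
    green intensities is returned as the threshold.
    """
    params = params or DetectionParams()
    frames = [detect_all(t, params) for t in tiles]
    cand = pd.concat(frames, ignore_index=True) if frames else _empty_regions()
    if len(cand) == 0:
        raise ValueError(f"no candidate grains found; need at least {n_dim} dim grains")
    values = cand["mean_green"].to_numpy(float)
    if np.unique(values).size > 1:
        try:
            split = threshold_otsu(values)
            dim = values[values < split]
            if dim.size == 0:
                dim = values
        except ValueError:
            dim = values
    else:
        dim = values
    if dim.size < n_dim:
        raise ValueError(
            f"only {dim.size} dim grains available, need {n_dim} "
            f"({n_dim - dim.size} short)"
        )
    rng = substream(seed, "calibrate-threshold")
    chosen = rng.choice(dim, size=n_dim, replace=False)
    return float(np.mean(chosen))


def combine_regions(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-tile region tables with globally unique region ids."""
    if not frames:
        return _empty_regions()
    df = pd.concat(frames, ignore_index=True)
    df["region_id"] = np.arange(len(df))
    return df
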
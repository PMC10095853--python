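"""Synthetic pollen fields and their rendering into multi-channel tiles.

The world model is a flat list of cells (pollen grains and sub-12-um dust
particles) with stage coordinates in micrometres, per-cell class and
fluorescence state.  Stage origin is the top-left corner of the irradiation
area, +x right, +y down; pixel indices are 0-based and a pixel ``i`` covers
the half-open interval ``[i * px, (i + 1) * px)`` um.

A field is generated once with the configured density / viability / target
statistics and can be rendered any number of times; rendering is a pure
function of (field state, imaging geometry, seed), which is what lets the
laser simulator re-render the post-irradiation state through the same code
path.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from .config import FULL_SCALE, FieldConfig, ImagingConfig
from .rng import substream

__all__ = [
    "CELL_COLUMNS",
    "CLASSES",
    "PackingError",
    "PollenField",
    "TileGrid",
    "ImageTile",
    "generate_field",
    "render_tiles",
    "stitch_tiles",
]

CLASSES = ("viable-nontarget", "viable-target", "dead", "dust")

CELL_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "diameter_um",
    "cls",
    "fda_on",
    "red_on",
    "displaced",
    "shrunken",
    "green_level",
]


class PackingError(RuntimeError):
    """Raised when the requested number of min-separated cells cannot be placed."""


@dataclass
class PollenField:
    """Ground truth: one row per cell, plus the stage extent of the area."""

    cells: pd.DataFrame
    width_um: float
    height_um: float
    config: FieldConfig | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.cells
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"field table missing columns: {missing}")
        if df["id"].duplicated().any():
            raise ValueError("cell ids must be unique")
        bad = set(df["cls"]) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown cell classes: {sorted(bad)}")
        dust = df[df["cls"] == "dust"]
        if (dust["diameter_um"] > 12.0).any():
            raise ValueError("dust must have diameter <= 12 um")
        dead = df[df["cls"] == "dead"]
        if dead["fda_on"].any():
            raise ValueError("dead cells cannot be FDA-positive")
        targets = df[df["cls"] == "viable-target"]
        if not targets["red_on"].all():
            raise ValueError("target cells must carry the red label")

    def copy(self) -> "PollenField":
        return PollenField(
            self.cells.copy(), self.width_um, self.height_um, self.config
        )

    @property
    def pollen(self) -> pd.DataFrame:
        """All non-dust cells."""
        return self.cells[self.cells["cls"] != "dust"]


@dataclass(frozen=True)
class TileGrid:
    """Row-major half-open tiling of the stage area."""

    n_rows: int
    n_cols: int
    tile_width_um: float
    tile_height_um: float

    @classmethod
    def for_field(cls, field: PollenField, imaging: ImagingConfig) -> "TileGrid":
        tw, th = imaging.tile_width_um, imaging.tile_height_um
        n_cols = field.width_um / tw
        n_rows = field.height_um / th
        if abs(n_cols - round(n_cols)) > 1e-9 or abs(n_rows - round(n_rows)) > 1e-9:
            raise ValueError(
                f"tiles of {tw} x {th} um do not cover a "
                f"{field.width_um} x {field.height_um} um field exactly"
            )
        return cls(int(round(n_rows)), int(round(n_cols)), tw, th)

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def tile_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def origin_um(self, tile_id: int) -> tuple[float, float]:
        row, col = divmod(tile_id, self.n_cols)
        return col * self.tile_width_um, row * self.tile_height_um

    def tile_of(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Tile id owning each stage point (half-open [x0, x0+w) intervals)."""
        col = np.floor(np.asarray(x_um) / self.tile_width_um).astype(int)
        row = np.floor(np.asarray(y_um) / self.tile_height_um).astype(int)
        return row * self.n_cols + col


@dataclass
class ImageTile:
    """One captured tile: per-channel uint16 arrays plus stage metadata."""

    tile_id: int
    row: int
    col: int
    x0_um: float
    y0_um: float
    pixel_size_um: float
    channels: dict[str, np.ndarray] = dc_field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------


def _place_separated(
    n: int,
    radii: np.ndarray,
    width: float,
    height: float,
    min_sep: float,
    rng: np.random.Generator,
    max_tries_per_cell: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throw ``n`` centres keeping pairwise distance >= ``min_sep``.

    Cells are kept fully inside the stage area (margin = radius).  Uses a
    uniform grid hash so placement is ~O(n) at the densities of interest.
    """
    xs = np.empty(n)
    ys = np.empty(n)
    if n == 0:
        return xs, ys
    cell = max(min_sep, 1e-9)
    buckets: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        r = radii[i]
        if width - 2 * r <= 0 or height - 2 * r <= 0:
            raise PackingError(
                f"cell radius {r:.1f} um does not fit a "
                f"{width} x {height} um area"
            )
        placed = False
        for _ in range(max_tries_per_cell):
            x = rng.uniform(r, width - r)
            y = rng.uniform(r, height - r)
            if min_sep > 0:
                gx, gy = int(x // cell), int(y // cell)
                ok = True
                for bx in range(gx - 1, gx + 2):
                    for by in range(gy - 1, gy + 2):
                        for j in buckets.get((bx, by), ()):
                            if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < min_sep**2:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                buckets.setdefault((gx, gy), []).append(i)
            xs[i], ys[i] = x, y
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place cell {i + 1}/{n} with min separation "
                f"{min_sep} um in a {width} x {height} um area "
                f"(density too high for the requested separation)"
            )
    return xs, ys


def generate_field(config: FieldConfig) -> PollenField:
    """Draw a ground-truth field with the configured statistics.

    Cell count is Poisson(density x area); each grain is viable with the
    configured probability, and viable grains carry the red target label with
    probability ``target_fraction_of_viable``.  A ``clump_fraction`` of grains
    is placed touching a previously placed grain (centre distance 0.9 x the
    sum of radii) instead of respecting ``min_separation_um``; sub-12-um dust
    particles are sprinkled uniformly on top.  Deterministic given
    ``config.rng_seed``.
    """
    seed = config.rng_seed
    r_count = substream(seed, "field-count")
    r_place = substream(seed, "field-place")
    r_class = substream(seed, "field-class")
    r_int = substream(seed, "field-intensity")
    im = config.intensity
    w, h = config.area_width_um, config.area_height_um

    n = int(r_count.poisson(config.density_per_mm2 * config.area_mm2))
    n_clump = int(round(config.clump_fraction * n))
    n_free = n - n_clump
    if n_free == 0 and n_clump > 0:  # need at least one host grain
        n_free, n_clump = 1, n_clump - 1

    diam = r_class.normal(config.diameter_mean_um, config.diameter_sd_um, size=n)
    diam = np.clip(diam, 12.5, None)  # grains always pass the dust filter

    xs, ys = _place_separated(
        n_free, diam[:n_free] / 2, w, h, config.min_separation_um, r_place
    )
    xs = np.concatenate([xs, np.zeros(n_clump)])
    ys = np.concatenate([ys, np.zeros(n_clump)])
    for k in range(n_free, n):
        host = int(r_place.integers(0, k))
        dist = 0.9 * (diam[k] / 2 + diam[host] / 2)
        theta = r_place.uniform(0, 2 * np.pi)
        r = diam[k] / 2
        xs[k] = np.clip(xs[host] + dist * np.cos(theta), r, w - r)
        ys[k] = np.clip(ys[host] + dist * np.sin(theta), r, h - r)

    viable = r_class.random(n) < config.viability_fraction
    target = viable & (r_class.random(n) < config.target_fraction_of_viable)
    cls = np.where(
        target, "viable-target", np.where(viable, "viable-nontarget", "dead")
    )

    fda_level = r_int.normal(im.viable_fda_mean, im.viable_fda_sd, size=n)
    fda_level = np.clip(
        fda_level, im.viable_fda_mean - 3 * im.viable_fda_sd, FULL_SCALE
    )
    green_level = np.where(viable, fda_level, im.autofluorescence_level)

    n_dust = int(r_count.poisson(config.dust_per_mm2 * config.area_mm2))
    lo, hi = config.dust_diameter_um
    dust_d = r_place.uniform(lo, hi, size=n_dust)
    dust_x = r_place.uniform(hi / 2, w - hi / 2, size=n_dust)
    dust_y = r_place.uniform(hi / 2, h - hi / 2, size=n_dust)

    cells = pd.DataFrame(
        {
            "id": np.arange(n + n_dust),
            "x_um": np.concatenate([xs, dust_x]),
            "y_um": np.concatenate([ys, dust_y]),
            "diameter_um": np.concatenate([diam, dust_d]),
            "cls": np.concatenate([cls, np.full(n_dust, "dust")]),
            "fda_on": np.concatenate([viable, np.zeros(n_dust, bool)]),
            "red_on": np.concatenate([target, np.zeros(n_dust, bool)]),
            "displaced": np.zeros(n + n_dust, bool),
            "shrunken": np.zeros(n + n_dust, bool),
            "green_level": np.concatenate(
                [green_level, np.full(n_dust, im.dust_green_level)]
            ),
        }
    )
    return PollenField(cells, w, h, config)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _cell_levels(field: PollenField) -> pd.DataFrame:
    """Per-cell rendered intensity per channel."""
    im = field.config.intensity if field.config else FieldConfig().intensity
    df = field.cells
    green = df["green_level"].to_numpy(float)
    red = np.where(df["red_on"], im.target_red_level, 0.0)
    bf = np.full(len(df), im.brightfield_cell_level)
    return pd.DataFrame({"green": green, "red": red, "brightfield": bf})


def render_tiles(
    field: PollenField, imaging: ImagingConfig, seed: int = 0
) -> list[ImageTile]:
    """Render the field into its grid of multi-channel 16-bit tiles.

    Each cell is a filled disk at its projected pixel position; a disk that
    straddles a tile boundary is rendered in every tile it touches, exactly
    as a tiled acquisition would capture it.  Per-tile Gaussian read noise is
    drawn from a substream keyed on (seed, tile id) and the result is clipped
    to the 16-bit range, so rendering is bit-reproducible given the seed.
    """
    grid = TileGrid.for_field(field, imaging)
    im = field.config.intensity if field.config else FieldConfig().intensity
    px = imaging.pixel_size_um
    df = field.cells
    x = df["x_um"].to_numpy(float)
    y = df["y_um"].to_numpy(float)
    d = df["diameter_um"].to_numpy(float)
    out_of_bounds = (
        (x < 0) | (x >= field.width_um) | (y < 0) | (y >= field.height_um)
    )
    if out_of_bounds.any():
        bad = df.loc[out_of_bounds, "id"].tolist()
        raise ValueError(f"cells outside the field bounds: {bad}")
    levels = _cell_levels(field)

    tw_px, th_px = imaging.tile_width_px, imaging.tile_height_px
    tiles: list[ImageTile] = []
    for tid in range(grid.n_tiles):
        row, col = divmod(tid, grid.n_cols)
        x0, y0 = grid.origin_um(tid)
        chans = {
            ch: np.full((th_px, tw_px), float(im.background_mean))
            for ch in imaging.channels
        }
        # cells whose disk bbox intersects this tile
        r_um = d / 2
        hit = (
            (x + r_um >= x0)
            & (x - r_um < x0 + grid.tile_width_um)
            & (y + r_um >= y0)
            & (y - r_um < y0 + grid.tile_height_um)
        )
        for i in np.flatnonzero(hit):
            cc = (x[i] - x0) / px - 0.5
            rr = (y[i] - y0) / px - 0.5
            rad = r_um[i] / px
            pix = _draw_disk((rr, cc), rad, shape=(th_px, tw_px))
            for ch in imaging.channels:
                lv = levels[ch].iloc[i] if ch in levels else 0.0
                if lv > 0:
                    np.maximum.at(chans[ch], pix, lv)
        rng = substream(seed, f"render-tile-{tid}")
        for ch in imaging.channels:
            sd = imaging.noise_sd.get(ch, 0.0)
            if sd > 0:
                chans[ch] = chans[ch] + rng.normal(0.0, sd, size=chans[ch].shape)
            chans[ch] = np.clip(chans[ch], 0, FULL_SCALE).astype(np.uint16)
        tiles.append(ImageTile(tid, row, col, x0, y0, px, chans))
    return tiles


def stitch_tiles(tiles: list[ImageTile]) -> ImageTile:
    """Assemble tiles into one mosaic tile covering the whole stage area.

    Tiles are half-open and non-overlapping, so stitching is a pure copy.
    The mosaic behaves like any other :class:`ImageTile` (tile id -1), which
    lets detection run globally so grains straddling tile boundaries are
    measured once instead of as two fragments.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    px = tiles[0].pixel_size_um
    th, tw = tiles[0].shape
    n_rows = max(t.row for t in tiles) + 1
    n_cols = max(t.col for t in tiles) + 1
    chans = {
        ch: np.zeros((n_rows * th, n_cols * tw), dtype=np.uint16)
        for ch in tiles[0].channels
    }
    for t in tiles:
        for ch, arr in t.channels.items():
            chans[ch][t.row * th : (t.row + 1) * th, t.col * tw : (t.col + 1) * tw] = arr
    return ImageTile(-1, 0, 0, 0.0, 0.0, px, chans)
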
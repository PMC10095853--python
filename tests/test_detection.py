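"""Region detection: thresholds, dust filter, targets, clumps, calibration."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label as sk_label

from pollenbeam import (
    DetectionParams,
    ImageTile,
    TileGrid,
    calibrate_threshold,
    detect_targets,
    detect_viable,
    flag_clumps,
    generate_field,
    render_tiles,
    stitch_tiles,
)
from pollenbeam.detect import detect_all, detect_regions

from conftest import flood_fill_components, manual_field, small_field_config
from test_field_synth import clopper_pearson


def blank_tile(size: int = 128, px: float = 1.0, value: int = 1000) -> ImageTile:
    chans = {
        ch: np.full((size, size), value, dtype=np.uint16)
        for ch in ("green", "red", "brightfield")
    }
    return ImageTile(0, 0, 0, 0.0, 0.0, px, chans)


def blob_tile(area_px: int, value: int = 20000) -> ImageTile:
    """A single connected blob of exactly ``area_px`` bright pixels."""
    tile = blank_tile()
    side = int(np.ceil(np.sqrt(area_px)))
    filled = 0
    for r in range(side):
        for c in range(side):
            if filled < area_px:
                tile.channels["green"][30 + r, 30 + c] = value
                filled += 1
    return tile


class TestDustFilter:
    @pytest.mark.parametrize(
        "area_px,kept",
        [
            (113, False),  # equivalent diameter 11.99 um <= 12: dust
            (114, True),  # 12.05 um > 12: a grain
        ],
    )
    def test_twelve_micron_filter_is_strict(self, area_px, kept, detection_params):
        regions = detect_viable(blob_tile(area_px), detection_params)
        assert (len(regions) == 1) is kept

    def test_blank_tile_empty(self, detection_params):
        assert len(detect_viable(blank_tile(), detection_params)) == 0

    def test_disks_kept_dust_dropped(self, imaging_noise_free, detection_params):
        """5 bright 25 um grains + 3 x 5 um dust specks -> exactly 5 regions."""
        cells = [
            dict(id=i, x_um=80.0 + 90 * i, y_um=100.0, diameter_um=25.0)
            for i in range(5)
        ]
        dust = [
            dict(
                id=10 + i,
                x_um=60.0 + 120 * i,
                y_um=300.0,
                diameter_um=5.0,
                cls="dust",
                fda_on=False,
                green_level=12000.0,
            )
            for i in range(3)
        ]
        field = manual_field(cells + dust)
        (tile,) = render_tiles(field, imaging_noise_free, seed=0)
        regions = detect_viable(tile, detection_params)
        assert len(regions) == 5
        got = regions.sort_values("x_um")[["x_um", "y_um"]].to_numpy()
        want = np.array([[c["x_um"], c["y_um"]] for c in cells])
        assert np.abs(got - want).max() <= 1.0  # centroids within 1 px


class TestOracleEquivalence:
    def test_labelling_matches_flood_fill(self, detection_params):
        """skimage components == brute-force flood fill on random tiles."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            tile = blank_tile(128)
            img = rng.choice([500, 15000], size=(128, 128), p=[0.8, 0.2])
            tile.channels["green"] = img.astype(np.uint16)
            mask = img > 9600
            ours = sk_label(mask, connectivity=2)
            oracle = flood_fill_components(mask, connectivity=2)
            assert ours.max() == oracle.max()
            # identical partitions (label ids may differ)
            pairs = set(zip(ours[mask].ravel(), oracle[mask].ravel()))
            assert len(pairs) == ours.max()

    def test_noise_free_precision_recall(self, imaging_noise_free, detection_params):
        field = generate_field(small_field_config(rng_seed=21, dust_per_mm2=20.0))
        tiles = render_tiles(field, imaging_noise_free, seed=0)
        regions = detect_viable(stitch_tiles(tiles), detection_params)
        truth = field.pollen[field.pollen["fda_on"]]
        assert len(regions) == len(truth)  # precision = recall = 1
        got = regions.sort_values(["x_um", "y_um"])[["x_um", "y_um"]].to_numpy()
        want = truth.sort_values(["x_um", "y_um"])[["x_um", "y_um"]].to_numpy()
        assert np.abs(got - want).max() <= 1.0


class TestTargets:
    def test_zero_red_not_target(self, detection_params):
        tile = blob_tile(400)
        regions = detect_viable(tile, detection_params)
        regions = detect_targets(regions, tile, detection_params)
        assert not regions["is_target"].any()

    def test_rendered_target_vs_nontarget(self, imaging_noise_free, detection_params):
        field = manual_field(
            [
                dict(id=0, x_um=100.0, y_um=100.0, cls="viable-target", red_on=True),
                dict(id=1, x_um=300.0, y_um=300.0),
            ]
        )
        (tile,) = render_tiles(field, imaging_noise_free, seed=0)
        regions = detect_targets(detect_viable(tile, detection_params), tile, detection_params)
        by_x = regions.sort_values("x_um")["is_target"].tolist()
        assert by_x == [True, False]

    def test_target_fraction_recovered_within_ci(self, imaging_small, detection_params):
        """A 5.8 %-target field yields a detected ratio inside the binomial CI."""
        cfg = small_field_config(
            area_width_um=2000, area_height_um=2000, rng_seed=31
        )
        field = generate_field(cfg)
        tiles = render_tiles(field, imaging_small, seed=1)
        regions = detect_all(stitch_tiles(tiles), detection_params)
        k = int((regions["is_viable"] & regions["is_target"]).sum())
        n = int(regions["is_viable"].sum())
        lo, hi = clopper_pearson(k, n)
        assert lo <= 0.058 <= hi

    def test_viability_fraction_recovered_within_ci(self, imaging_small, detection_params):
        cfg = small_field_config(area_width_um=2000, area_height_um=2000, rng_seed=32)
        field = generate_field(cfg)
        regions = detect_all(
            stitch_tiles(render_tiles(field, imaging_small, seed=2)), detection_params
        )
        k = int(regions["is_viable"].sum())
        lo, hi = clopper_pearson(k, len(regions))
        assert lo <= 0.77 <= hi


class TestClumps:
    def test_single_region_tile_is_separated(self, detection_params):
        tile = blob_tile(400)
        regions, separated = flag_clumps(detect_viable(tile, detection_params), detection_params)
        assert bool(separated.loc[0]) is True

    def test_overlapping_pair_flagged(self, imaging_noise_free, detection_params):
        """Two touching 25 um grains merge into one region flagged as a clump."""
        singles = [
            dict(id=i, x_um=80.0 + 90 * i, y_um=100.0) for i in range(4)
        ]
        pair = [
            dict(id=10, x_um=200.0, y_um=350.0),
            dict(id=11, x_um=220.0, y_um=350.0),  # 20 um apart: overlapping
        ]
        field = manual_field(singles + pair)
        (tile,) = render_tiles(field, imaging_noise_free, seed=0)
        regions, separated = flag_clumps(detect_viable(tile, detection_params), detection_params)
        assert len(regions) == 5  # pair merged
        assert int(regions["is_clump"].sum()) == 1
        assert regions.loc[regions["is_clump"], "area_px"].iloc[0] == regions["area_px"].max()
        assert bool(separated.loc[0]) is False

    def test_separation_fraction_monotone_in_clumping(self, imaging_small, detection_params):
        def sep_fraction(clump, seed):
            cfg = small_field_config(clump_fraction=clump, rng_seed=seed)
            field = generate_field(cfg)
            grid = TileGrid.for_field(field, imaging_small)
            mosaic = stitch_tiles(render_tiles(field, imaging_small, seed=seed))
            regions = detect_viable(mosaic, detection_params)
            regions["tile_id"] = grid.tile_of(
                regions["x_um"].to_numpy(), regions["y_um"].to_numpy()
            )
            _, separated = flag_clumps(regions, detection_params)
            return separated.mean() if len(separated) else 1.0

        seeds = range(6)
        clean = np.mean([sep_fraction(0.0, s) for s in seeds])
        clumpy = np.mean([sep_fraction(0.3, s) for s in seeds])
        assert clean > clumpy


class TestCalibration:
    def test_constant_dim_grains(self, imaging_noise_free):
        """All sampled grains at one intensity -> that intensity is the threshold."""
        cells = [
            dict(
                id=i,
                x_um=80.0 + 80 * (i % 5),
                y_um=80.0 + 80 * (i // 5),
                cls="dead",
                fda_on=False,
                green_level=3000.0,
            )
            for i in range(12)
        ]
        field = manual_field(cells)
        tiles = render_tiles(field, imaging_noise_free, seed=0)
        thr = calibrate_threshold(tiles, n_dim=10, seed=0)
        assert thr == pytest.approx(3000.0, abs=1.0)

    def test_two_population_separation(self, imaging_noise_free):
        """Dim mode ~3,000 vs bright mode ~20,000: threshold splits them."""
        cfg = small_field_config(rng_seed=41, viability_fraction=0.5)
        field = generate_field(cfg)
        tiles = render_tiles(field, imaging_noise_free, seed=0)
        thr = calibrate_threshold(tiles, n_dim=10, seed=3)
        regions = detect_all(stitch_tiles(tiles), DetectionParams())
        bright = regions.loc[regions["mean_green"] > 10000, "mean_green"]
        assert (bright > thr).all()
        assert thr < 10000

    def test_shortfall_is_named(self, imaging_noise_free):
        field = manual_field([dict(id=0, x_um=100.0, y_um=100.0, cls="dead", fda_on=False, green_level=3000.0)])
        tiles = render_tiles(field, imaging_noise_free, seed=0)
        with pytest.raises(ValueError, match="need 10"):
            calibrate_threshold(tiles, n_dim=10, seed=0)

    def test_default_samples_ten_grains(self):
        import inspect

        assert inspect.signature(calibrate_threshold).parameters["n_dim"].default == 10


class TestMetadata:
    def test_missing_pixel_size_is_hard_error(self, detection_params):
        tile = blank_tile()
        tile.pixel_size_um = 0.0
        with pytest.raises(ValueError, match="pixel-size"):
            detect_viable(tile, detection_params)

    def test_missing_channel_rejected(self, detection_params):
        tile = blank_tile()
        del tile.channels["green"]
        with pytest.raises(ValueError, match="green"):
            detect_regions(tile, detection_params, "green", 9600)
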
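"""Five-step virtual isolation run: capture, detect, mask, irradiate, re-capture.

``run_pipeline`` binds the stages into the automated loop: (a) render the
field into tiles, (b) detect living pollen and record stage positions,
(c) detect targets and mask their 60 um neighbourhoods, (d) irradiate every
unmasked viable non-target at its centre, (e) re-capture and re-detect to
score the disruption — then assemble the enrichment and per-tile reports.

Detection runs on the stitched mosaic (tiles are half-open and
non-overlapping) so grains straddling tile boundaries are measured once;
regions are then assigned to the tile owning their centroid, preserving the
per-tile bookkeeping of the original loop.  All randomness derives from the
single config seed through named substreams, so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .detect import calibrate_threshold, detect_all, flag_clumps
from .field import ImageTile, PollenField, TileGrid, generate_field, render_tiles, stitch_tiles
from .plan import IrradiationPlan, MaskZone, build_masks, order_shots, plan_irradiation
from .report import EnrichmentReport, TileReport, build_reports
from .rng import subseed
from .zap import ApplyResult, apply_plan, rerender_post

__all__ = ["PipelineResult", "run_pipeline", "detect_sample"]

log = logging.getLogger("pollenbeam.pipeline")


@dataclass
class PipelineResult:
    config: PipelineConfig
    field: PollenField
    grid: TileGrid
    tiles: list[ImageTile]
    fda_threshold: float
    pre_regions: pd.DataFrame
    separated: pd.Series
    masks: list[MaskZone]
    plan: IrradiationPlan
    apply_result: ApplyResult
    post_field: PollenField
    post_tiles: list[ImageTile]
    post_regions: pd.DataFrame
    report: EnrichmentReport
    tile_report: TileReport


def detect_sample(tiles: list[ImageTile], params, grid: TileGrid) -> tuple[pd.DataFrame, pd.Series]:
    """Detect all grains on the stitched sample and flag clumps per tile."""
    mosaic = stitch_tiles(tiles)
    regions = detect_all(mosaic, params)
    if len(regions):
        regions["tile_id"] = grid.tile_of(
            regions["x_um"].to_numpy(), regions["y_um"].to_numpy()
        )
        regions["region_id"] = np.arange(len(regions))
    regions, separated = flag_clumps(regions, params)
    return regions, separated


def _stage(name: str, **counts) -> None:
    log.info("%s: %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full virtual run; optionally write every artifact.

    Raises with the stage name on any stage failure.  With an ``out_dir``
    the artifact tree (field/tiles/regions/plan/post-field/post-tiles/
    post-regions/reports) is written and is byte-identical across runs with
    the same config.
    """
    seed = config.seed
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    field_cfg = config.field.model_copy(update={"rng_seed": subseed(seed, "field")})
    field = generate_field(field_cfg)
    _stage("generate", cells=len(field.cells), pollen=len(field.pollen))

    grid = TileGrid.for_field(field, config.imaging)
    tiles = render_tiles(field, config.imaging, seed=subseed(seed, "render-pre"))
    _stage("capture-pre", tiles=len(tiles))

    params = config.detection
    if config.calibrate_fda_threshold:
        thr = calibrate_threshold(
            tiles, config.calibrate_n_dim, seed=subseed(seed, "calibrate"), params=params
        )
        params = params.model_copy(update={"fda_threshold": thr})
        _stage("calibrate", fda_threshold=round(thr, 1))

    try:
        pre_regions, separated = detect_sample(tiles, params, grid)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage detect-pre failed: {exc}") from exc
    _stage(
        "detect-pre",
        total=len(pre_regions),
        fda_pos=int(pre_regions["is_viable"].sum()),
        targets=int((pre_regions["is_viable"] & pre_regions["is_target"]).sum()),
    )

    targets = pre_regions[pre_regions["is_target"]]
    masks = build_masks(targets, config.mask_diameter_um)
    plan = plan_irradiation(pre_regions, masks, config.laser)
    plan = order_shots(plan, grid)
    n_masked = int(
        (pre_regions["is_viable"] & ~pre_regions["is_target"]).sum() - len(plan)
    )
    _stage("plan", masks=len(masks), shots=len(plan), masked=n_masked)

    model = config.disruption.model_copy(update={"rng_seed": subseed(seed, "zap")})
    applied = apply_plan(
        field, plan, model, config.elapsed_s, config.field.target_attrition_prob
    )
    post_field = applied.field
    _stage(
        "irradiate",
        shots=len(plan),
        missed=applied.n_missed,
        disrupted=int(applied.shot_log["disrupted"].sum()) if len(applied.shot_log) else 0,
    )

    post_tiles = rerender_post(post_field, config.imaging, seed=subseed(seed, "render-post"))
    try:
        post_regions, _ = detect_sample(post_tiles, params, grid)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage detect-post failed: {exc}") from exc
    _stage(
        "detect-post",
        total=len(post_regions),
        fda_pos=int(post_regions["is_viable"].sum()),
    )

    report, tile_report = build_reports(
        pre_regions, plan, post_regions, area_mm2=field_cfg.area_mm2, separated=separated
    )
    _stage(
        "report",
        pre_ratio=report.pre_target_ratio_pct,
        post_ratio=report.post_target_ratio_pct,
        fold=report.fold_enrichment,
    )

    result = PipelineResult(
        config=config,
        field=field,
        grid=grid,
        tiles=tiles,
        fda_threshold=params.fda_threshold,
        pre_regions=pre_regions,
        separated=separated,
        masks=masks,
        plan=plan,
        apply_result=applied,
        post_field=post_field,
        post_tiles=post_tiles,
        post_regions=post_regions,
        report=report,
        tile_report=tile_report,
    )
    if out is not None:
        _write_artifacts(result, out)
    return result


def _write_artifacts(res: PipelineResult, out: Path) -> None:
    pio.write_field_csv(res.field, out / "field.csv")
    pio.write_tiles(res.tiles, out / "tiles_pre")
    pio.write_regions_csv(res.pre_regions, out / "regions_pre.csv")
    pio.write_plan_json(res.plan, out / "plan.json")
    pio.write_field_csv(res.post_field, out / "field_post.csv")
    pio.write_tiles(res.post_tiles, out / "tiles_post")
    pio.write_regions_csv(res.post_regions, out / "regions_post.csv")
    res.tile_report.to_frame().to_csv(out / "report_tiles.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(res.report.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    sep = res.separated.rename_axis("tile_id").reset_index()
    sep.to_csv(out / "tile_separation.csv", index=False)
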
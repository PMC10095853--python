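"""Laser-disruption simulation: FDA decay, shrinkage, displacement, misses.

The biological response is reduced to what downstream detection can see:
after a successful shot the grain's FDA fluorescence disappears once the
power/exposure-dependent decay time has elapsed (a step, not a bleach
curve), the grain shrinks, and at extreme power it is physically displaced.
Protected targets may still lose FDA spontaneously (developmental arrest is
modelled as a per-target attrition probability); everything else is left
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import DisruptionModel, FieldConfig, ImagingConfig
from .field import ImageTile, PollenField, render_tiles
from .plan import IrradiationPlan
from .rng import substream

__all__ = ["NEVER", "DecayResult", "ApplyResult", "decay_time", "apply_plan", "rerender_post"]

#: Sentinel decay time for powers at which FDA fluorescence never disappears.
NEVER = math.inf


class DecayResult(NamedTuple):
    time_s: float  # seconds until FDA loss; ``NEVER`` if it persists
    displaced: bool  # grain physically jumps at extreme power


def _breakpoint_times(model: DisruptionModel) -> tuple[np.ndarray, np.ndarray]:
    """Decay times at the characterised powers, drawn once per model seed.

    Draws are keyed on the model seed only, so repeated queries are
    consistent and decay time stays non-increasing across the power axis.
    """
    lo48, hi48 = model.t48_range_s
    t48 = float(substream(model.rng_seed, "decay-48").uniform(lo48, hi48))
    t96 = float(model.t96_s)
    # uniform in (0, cap]: cap * (1 - u) with u in [0, 1)
    cap = min(model.t145_max_s, t96)
    t145 = cap * (1.0 - float(substream(model.rng_seed, "decay-145").random()))
    powers = np.array([model.never_below_mw, 96.0, 145.0, model.displace_at_mw])
    times = np.array([t48, t96, t145, 0.0])
    return powers, times


def decay_time(
    power_mw: float, exposure_ms: float, model: DisruptionModel
) -> DecayResult:
    """Seconds until the FDA signal of an irradiated grain disappears.

    Below 48 mW the signal persists indefinitely (``NEVER``); at 48 mW loss
    takes a uniform 165-225 s; at 145 mW it is within 42.5 s; at 194 mW it
    is instantaneous and the grain is displaced.  Between characterised
    powers the time is interpolated log-linearly; no extrapolation outside
    the 24-194 mW / 1-20 ms ranges that were examined.
    """
    p_lo, p_hi = model.power_range_mw
    if not (p_lo <= power_mw <= p_hi):
        raise ValueError(
            f"power {power_mw} mW outside the characterised range "
            f"[{p_lo}, {p_hi}] mW; refusing to extrapolate"
        )
    e_lo, e_hi = model.exposure_range_ms
    if not (e_lo <= exposure_ms <= e_hi):
        raise ValueError(
            f"exposure {exposure_ms} ms outside the characterised range "
            f"[{e_lo}, {e_hi}] ms; refusing to extrapolate"
        )
    displaced = power_mw >= model.displace_at_mw
    if power_mw < model.never_below_mw:
        return DecayResult(NEVER, displaced)
    powers, times = _breakpoint_times(model)
    t = float(np.interp(np.log(power_mw), np.log(powers), times))
    if model.exposure_exponent > 0:
        t *= (10.0 / exposure_ms) ** model.exposure_exponent
    return DecayResult(t, displaced)


@dataclass
class ApplyResult:
    """Post-irradiation field plus a per-shot log."""

    field: PollenField
    shot_log: pd.DataFrame  # region_id, cell_id, hit, success, decay_s, disrupted, displaced

    @property
    def n_missed(self) -> int:
        return int((~self.shot_log["hit"]).sum()) if len(self.shot_log) else 0


def apply_plan(
    field: PollenField,
    plan: IrradiationPlan,
    model: DisruptionModel,
    elapsed_s: float,
    target_attrition_prob: float | None = None,
) -> ApplyResult:
    """Execute a plan against the ground-truth field.

    Each shot resolves to the nearest cell within half that cell's diameter
    (otherwise it is logged as a miss).  With probability ``success_prob``
    the hit grain's decay clock starts; once ``elapsed_s`` reaches it the
    grain is FDA-negative and shrunken, and at displacement-level power it
    additionally jumps 20-60 um in a random direction.  Cell count is
    conserved.  Deterministic given the model seed.
    """
    post = field.copy()
    cells = post.cells
    if target_attrition_prob is None:
        cfg = field.config
        target_attrition_prob = cfg.target_attrition_prob if cfg else 0.0
    autofl = (field.config or FieldConfig()).intensity.autofluorescence_level

    rng_shot = substream(model.rng_seed, "shots")
    rng_jump = substream(model.rng_seed, "displacement")
    log_rows: list[dict] = []
    if len(plan.shots):
        xy = cells[["x_um", "y_um"]].to_numpy(float)
        tree = cKDTree(xy)
        radii = cells["diameter_um"].to_numpy(float) / 2
        laser = plan.laser
        for shot in plan.shots.itertuples():
            dist, j = tree.query([shot.x_um, shot.y_um])
            hit = bool(dist <= radii[j])
            success = bool(rng_shot.random() < model.success_prob)
            row = {
                "region_id": int(shot.region_id),
                "cell_id": int(cells["id"].iloc[j]) if hit else -1,
                "hit": hit,
                "success": hit and success,
                "decay_s": np.nan,
                "disrupted": False,
                "displaced": False,
            }
            if hit and success:
                t, displaced = decay_time(laser.focal_power_mw, laser.exposure_ms, model)
                row["decay_s"] = t
                if elapsed_s >= t:
                    row["disrupted"] = True
                    idx = cells.index[j]
                    cells.loc[idx, "fda_on"] = False
                    cells.loc[idx, "green_level"] = autofl
                    cells.loc[idx, "shrunken"] = True
                    cells.loc[idx, "diameter_um"] *= model.shrink_factor
                    if displaced:
                        row["displaced"] = True
                        cells.loc[idx, "displaced"] = True
                        jump = rng_jump.uniform(20.0, 60.0)
                        theta = rng_jump.uniform(0, 2 * np.pi)
                        r = float(cells.loc[idx, "diameter_um"]) / 2
                        cells.loc[idx, "x_um"] = float(
                            np.clip(
                                cells.loc[idx, "x_um"] + jump * np.cos(theta),
                                r,
                                post.width_um - r,
                            )
                        )
                        cells.loc[idx, "y_um"] = float(
                            np.clip(
                                cells.loc[idx, "y_um"] + jump * np.sin(theta),
                                r,
                                post.height_um - r,
                            )
                        )
            log_rows.append(row)

    # spontaneous FDA loss of protected targets
    if target_attrition_prob > 0:
        rng_attr = substream(model.rng_seed, "attrition")
        shot_cells = {r["cell_id"] for r in log_rows if r["hit"]}
        is_target = (cells["cls"] == "viable-target") & cells["fda_on"]
        for idx in cells.index[is_target]:
            if int(cells.loc[idx, "id"]) in shot_cells:
                continue
            if rng_attr.random() < target_attrition_prob:
                cells.loc[idx, "fda_on"] = False
                cells.loc[idx, "green_level"] = autofl

    log = pd.DataFrame(
        log_rows,
        columns=[
            "region_id",
            "cell_id",
            "hit",
            "success",
            "decay_s",
            "disrupted",
            "displaced",
        ],
    )
    post.validate()
    return ApplyResult(post, log)


def rerender_post(
    field: PollenField, imaging: ImagingConfig, seed: int = 0
) -> list[ImageTile]:
    """Re-capture the irradiated area (delegates to the field renderer).

    FDA-negative grains render at autofluorescence level (below the
    positivity threshold) and shrunken grains at their reduced diameter, so
    running detection on the result assesses the disruption outcome.
    """
    return render_tiles(field, imaging, seed=seed)
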
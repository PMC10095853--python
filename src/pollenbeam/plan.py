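"""Irradiation planning: mask target neighbourhoods, shoot everything else.

Given the detected region list, the planner protects each target grain with
a circular exclusion zone (default diameter 60 um, centred on the target
centroid) and emits exactly one laser shot at the centroid of every viable,
non-target region whose centroid lies outside every zone.  Mask membership
is evaluated on the shot point (the centroid) and a centre exactly on the
zone boundary counts as masked — the conservative reading that favours
protecting targets.  FDA-negative regions and dust never enter a plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .config import LaserSettings
from .field import TileGrid

__all__ = [
    "MaskZone",
    "IrradiationPlan",
    "SHOT_COLUMNS",
    "build_masks",
    "masked_mask",
    "plan_irradiation",
    "order_shots",
]

SHOT_COLUMNS = ["region_id", "tile_id", "x_um", "y_um"]


@dataclass(frozen=True)
class MaskZone:
    """Circular exclusion zone around one target grain."""

    x_um: float
    y_um: float
    diameter_um: float = 60.0

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("mask diameter must be positive")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2


@dataclass
class IrradiationPlan:
    """Ordered list of shot coordinates plus the laser operating point."""

    laser: LaserSettings
    shots: pd.DataFrame = dc_field(
        default_factory=lambda: pd.DataFrame(columns=SHOT_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in SHOT_COLUMNS if c not in self.shots.columns]
        if missing:
            raise ValueError(f"shot table missing columns: {missing}")
        if self.shots["region_id"].duplicated().any():
            raise ValueError("region ids must be unique within a plan")

    def __len__(self) -> int:
        return len(self.shots)

    def validate_safety(self, masks: list[MaskZone]) -> None:
        """Assert no shot lies within any exclusion zone (brute force)."""
        if len(self.shots) == 0 or not masks:
            return
        sx = self.shots["x_um"].to_numpy(float)
        sy = self.shots["y_um"].to_numpy(float)
        for m in masks:
            d2 = (sx - m.x_um) ** 2 + (sy - m.y_um) ** 2
            if (d2 <= m.radius_um**2).any():
                bad = self.shots["region_id"].to_numpy()[d2 <= m.radius_um**2]
                raise ValueError(
                    f"shots {bad.tolist()} fall inside the exclusion zone at "
                    f"({m.x_um:.1f}, {m.y_um:.1f})"
                )


def build_masks(
    targets: pd.DataFrame, mask_diameter_um: float = 60.0
) -> list[MaskZone]:
    """One exclusion zone per target region, centred on its centroid."""
    if len(targets) and not targets["is_target"].all():
        bad = targets.loc[~targets["is_target"], "region_id"].tolist()
        raise ValueError(f"non-target regions passed to build_masks: {bad}")
    return [
        MaskZone(float(r.x_um), float(r.y_um), mask_diameter_um)
        for r in targets.itertuples()
    ]


def masked_mask(regions: pd.DataFrame, masks: list[MaskZone]) -> np.ndarray:
    """Boolean array: region centroid inside (or on) any exclusion zone."""
    out = np.zeros(len(regions), dtype=bool)
    if not masks or len(regions) == 0:
        return out
    x = regions["x_um"].to_numpy(float)
    y = regions["y_um"].to_numpy(float)
    for m in masks:
        out |= (x - m.x_um) ** 2 + (y - m.y_um) ** 2 <= m.radius_um**2
    return out


def plan_irradiation(
    regions: pd.DataFrame, masks: list[MaskZone], laser: LaserSettings
) -> IrradiationPlan:
    """Shots = viable, non-target regions with unmasked centroids, once each.

    A region inside two overlapping zones is still excluded exactly once
    (set semantics); regions without stage coordinates are rejected.
    """
    if regions[["x_um", "y_um"]].isna().any().any():
        bad = regions.loc[
            regions[["x_um", "y_um"]].isna().any(axis=1), "region_id"
        ].tolist()
        raise ValueError(f"regions without stage coordinates: {bad}")
    eligible = regions["is_viable"] & ~regions["is_target"] & ~masked_mask(
        regions, masks
    )
    shots = regions.loc[eligible, SHOT_COLUMNS].reset_index(drop=True)
    plan = IrradiationPlan(laser, shots)
    plan.validate_safety(masks)
    return plan


def order_shots(plan: IrradiationPlan, grid: TileGrid) -> IrradiationPlan:
    """Order shots for stage travel: tiles row-major, nearest-neighbour within.

    Within each tile the chain starts from the tile origin and greedily hops
    to the nearest remaining shot; if the greedy chain ever comes out longer
    than the input order (possible for adversarial layouts), the input order
    is kept, so the within-tile path is never lengthened.
    """
    shots = plan.shots
    if len(shots) <= 1:
        return IrradiationPlan(plan.laser, shots.reset_index(drop=True))
    ordered: list[pd.DataFrame] = []
    for tid in sorted(shots["tile_id"].unique()):
        block = shots[shots["tile_id"] == tid].reset_index(drop=True)
        ox, oy = grid.origin_um(int(tid))
        xs = block["x_um"].to_numpy(float)
        ys = block["y_um"].to_numpy(float)
        remaining = list(range(len(block)))
        order: list[int] = []
        cx, cy = ox, oy
        while remaining:
            d2 = [(xs[i] - cx) ** 2 + (ys[i] - cy) ** 2 for i in remaining]
            k = int(np.argmin(d2))
            i = remaining.pop(k)
            order.append(i)
            cx, cy = xs[i], ys[i]
        if _path_length(xs, ys, ox, oy, order) > _path_length(
            xs, ys, ox, oy, list(range(len(block)))
        ):
            order = list(range(len(block)))
        ordered.append(block.iloc[order])
    out = pd.concat(ordered, ignore_index=True)
    return IrradiationPlan(plan.laser, out)


def _path_length(
    xs: np.ndarray, ys: np.ndarray, ox: float, oy: float, order: list[int]
) -> float:
    px = np.concatenate([[ox], xs[order]])
    py = np.concatenate([[oy], ys[order]])
    return float(np.sum(np.hypot(np.diff(px), np.diff(py))))
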
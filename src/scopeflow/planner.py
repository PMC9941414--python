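"""Tiling and timelapse planning.

A tile grid covers an extended field of view with overlapping camera
FOVs: adjacent tiles are spaced ``fov·(1 − overlap)`` µm apart so that a
fraction ``overlap`` of each tile is shared with its neighbor and the
mosaic can be aligned post hoc, relaxing the demand on stage precision.
The canonical configuration — 5×5 tiles of 38 µm at 14 % overlap — spans
168.7 µm, covering a 160 µm target field.

Per-tile focus (z) registration and skip annotation replace the
interactive widefield step of a sessions-based workflow: a table of
(tile, z, skip) entries is applied to the plan, and skipped tiles are
excluded from every visit sequence.  A timelapse plan cycles the
(unskipped) tile order N times with a settle delay after each move.

Coordinate convention (shared with the mosaicking stage): stage x grows
rightward (image columns), stage y grows downward (image rows); tile
index (i, j) is 0-based (column, row); visits are row-major.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

__all__ = [
    "StageTarget",
    "TilePlan",
    "TimelapsePlan",
    "plan_grid",
    "mosaic_extent_um",
    "apply_registration",
    "plan_timelapse",
    "plan_to_json",
    "plan_from_json",
]


@dataclass(frozen=True)
class StageTarget:
    """One grid position: tile index (i=column, j=row) and stage µm."""

    tile_index: tuple[int, int]
    x_um: float
    y_um: float
    z_um: float = 0.0
    skip: bool = False

    def __post_init__(self) -> None:
        for v in (self.x_um, self.y_um, self.z_um):
            if not math.isfinite(v):
                raise ValueError("stage coordinates must be finite")

    def to_dict(self) -> dict:
        return {
            "tile_index": list(self.tile_index),
            "x_um": self.x_um,
            "y_um": self.y_um,
            "z_um": self.z_um,
            "skip": self.skip,
        }


@dataclass(frozen=True)
class TilePlan:
    """An nx×ny grid of stage targets with fractional overlap."""

    nx: int
    ny: int
    fov_um: float
    overlap_frac: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    targets: tuple[StageTarget, ...] = ()

    @property
    def step_um(self) -> float:
        return self.fov_um * (1.0 - self.overlap_frac)

    @property
    def active_targets(self) -> tuple[StageTarget, ...]:
        return tuple(t for t in self.targets if not t.skip)


@dataclass(frozen=True)
class TimelapsePlan:
    """N cyclic repetitions of a tile plan's visit order."""

    n_lapses: int
    tiles: TilePlan
    settle_s: float = 1.0

    @property
    def visits(self) -> tuple[tuple[int, StageTarget], ...]:
        """(lapse, target) pairs in execution order; skips excluded."""
        active = self.tiles.active_targets
        return tuple((t, tgt) for t in range(self.n_lapses) for tgt in active)


def plan_grid(
    nx: int,
    ny: int,
    fov_um: float,
    overlap_frac: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
    z_map: Callable[[int, int], float] | None = None,
) -> TilePlan:
    """Build an nx×ny tile grid.

    Target (i, j) sits at ``origin + (i·step, j·step)`` with
    ``step = fov·(1 − overlap)``; z from ``z_map(i, j)`` (default 0).
    Visit order is row-major (j outer, i inner).
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    if fov_um <= 0:
        raise ValueError("fov_um must be > 0")
    step = fov_um * (1.0 - overlap_frac)
    x0, y0 = origin_um
    targets = tuple(
        StageTarget(
            tile_index=(i, j),
            x_um=x0 + i * step,
            y_um=y0 + j * step,
            z_um=float(z_map(i, j)) if z_map is not None else 0.0,
        )
        for j in range(ny)
        for i in range(nx)
    )
    return TilePlan(
        nx=nx, ny=ny, fov_um=fov_um, overlap_frac=overlap_frac,
        origin_um=tuple(origin_um), targets=targets,
    )


def mosaic_extent_um(n: int, fov_um: float, overlap_frac: float) -> float:
    """Mosaic span along one axis, first tile start to last tile end:
    ``n·fov − (n−1)·overlap·fov``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * fov_um - (n - 1) * overlap_frac * fov_um


def apply_registration(
    plan: TilePlan,
    registrations: Sequence[tuple[tuple[int, int], float, bool]],
) -> TilePlan:
    """Apply a (tile_index, z_um, skip) table to a plan.

    The headless stand-in for interactive focus registration: each entry
    sets a tile's focus position and/or marks it skipped (no biological
    content); unregistered tiles keep their defaults.
    """
    valid = {t.tile_index for t in plan.targets}
    updates: dict[tuple[int, int], tuple[float, bool]] = {}
    for tile_index, z_um, skip in registrations:
        tile_index = tuple(tile_index)
        if tile_index not in valid:
            raise ValueError(f"unknown tile_index {tile_index} for {plan.nx}x{plan.ny} grid")
        updates[tile_index] = (float(z_um), bool(skip))
    new_targets = tuple(
        replace(t, z_um=updates[t.tile_index][0], skip=updates[t.tile_index][1])
        if t.tile_index in updates
        else t
        for t in plan.targets
    )
    return replace(plan, targets=new_targets)


def plan_timelapse(tiles: TilePlan, n_lapses: int, settle_s: float = 1.0) -> TimelapsePlan:
    """Cycle the (unskipped) tile order ``n_lapses`` times; ``settle_s``
    applies after every stage movement."""
    if n_lapses < 1:
        raise ValueError("n_lapses must be >= 1")
    if settle_s < 0:
        raise ValueError("settle_s must be >= 0")
    return TimelapsePlan(n_lapses=n_lapses, tiles=tiles, settle_s=settle_s)


# ---------------------------------------------------------------------------
# JSON serialization (the form demo scripts consume via the control API)
# ---------------------------------------------------------------------------


def plan_to_json(plan: TilePlan) -> str:
    return json.dumps(
        {
            "nx": plan.nx,
            "ny": plan.ny,
            "fov_um": plan.fov_um,
            "overlap_frac": plan.overlap_frac,
            "origin_um": list(plan.origin_um),
            "targets": [t.to_dict() for t in plan.targets],
        },
        indent=1,
    )


def plan_from_json(text: str | Path) -> TilePlan:
    if isinstance(text, Path):
        text = text.read_text(encoding="utf-8")
    d = json.loads(text)
    targets = tuple(
        StageTarget(
            tile_index=tuple(t["tile_index"]),
            x_um=t["x_um"],
            y_um=t["y_um"],
            z_um=t.get("z_um", 0.0),
            skip=t.get("skip", False),
        )
        for t in d["targets"]
    )
    return TilePlan(
        nx=d["nx"],
        ny=d["ny"],
        fov_um=d["fov_um"],
        overlap_frac=d["overlap_frac"],
        origin_um=tuple(d["origin_um"]),
        targets=targets,
    )
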
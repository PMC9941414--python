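"""Orchestrating viewer unit: layer registry and mosaic assembly.

A headless stand-in for an interactive viewer: reconstructed tiles
arriving in the ``rec`` folder are registered as ordered named layers
with their metadata (dumpable as JSON for inspection), then assembled
into a mosaic by nominal stage-offset placement — each tile is pasted at
``round((stage − min stage)/pixel_size)`` pixels on a shared canvas.
Cross-correlation refinement is deliberately out of scope; instead an
overlap-consistency metric (RMS difference over each pair's shared
region) quantifies how well the nominal placement agrees, i.e. when
refinement would actually be needed.

Convention (same as planning): stage x → canvas columns, stage y →
canvas rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import tifffile

from scopeflow.acquisition import AcquisitionMetadata
from scopeflow.reconstruction import ReconParams, ReconstructedTile, read_ome_zarr

__all__ = [
    "LayerRegistry",
    "MosaicLayout",
    "register_layer",
    "load_reconstructed",
    "compute_layout",
    "assemble_mosaic",
    "overlap_consistency",
]

logger = logging.getLogger(__name__)


@dataclass
class LayerEntry:
    name: str
    image: np.ndarray
    metadata: dict
    source_path: Path
    added_at: datetime


@dataclass
class LayerRegistry:
    """Ordered, uniquely named image layers (arrival order preserved)."""

    entries: list[LayerEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def has_path(self, path: Path) -> bool:
        path = Path(path).resolve()
        return any(Path(e.source_path).resolve() == path for e in self.entries)

    def to_json(self) -> str:
        """Inspectable dump: layer names, sources, metadata (no pixels)."""
        return json.dumps(
            [
                {
                    "name": e.name,
                    "source": str(e.source_path),
                    "added_at": e.added_at.isoformat(timespec="milliseconds"),
                    "shape": list(e.image.shape),
                    "metadata": e.metadata,
                }
                for e in self.entries
            ],
            indent=1,
        )


def load_reconstructed(path: Path) -> tuple[np.ndarray, dict]:
    """Read a reconstructed tile (TIFF or OME-Zarr) and its metadata."""
    path = Path(path)
    if path.is_dir():  # OME-Zarr
        image, attrs = read_ome_zarr(path)
        metadata = json.loads(attrs) if attrs else {}
    else:
        with tifffile.TiffFile(path) as tf:
            image = tf.asarray()
            desc = tf.pages[0].description
        try:
            metadata = json.loads(desc) if desc else {}
        except json.JSONDecodeError:
            metadata = {}
        if isinstance(metadata, dict) and set(metadata) <= {"shape"}:
            metadata = {}  # writer default shape tag, not experiment metadata
    return np.asarray(image), metadata


def register_layer(registry: LayerRegistry, path: Path) -> LayerRegistry:
    """Append a reconstructed image as a named layer.

    The name is the filename stem; re-adding an already registered path is
    ignored with a warning (idempotent).  A file without embedded metadata
    gets an empty metadata block and a warning.  Mutates and returns the
    registry.
    """
    path = Path(path)
    if registry.has_path(path):
        logger.warning("layer already registered, ignoring: %s", path)
        return registry
    image, metadata = load_reconstructed(path)
    if not metadata:
        logger.warning("no embedded metadata in %s", path)
    name = path.name
    for ext in (".tiff", ".tif", ".zarr"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    base, k = name, 1
    while name in registry.names:
        name = f"{base} [{k}]"
        k += 1
    registry.entries.append(
        LayerEntry(name=name, image=image, metadata=metadata,
                   source_path=path, added_at=datetime.now())
    )
    return registry


@dataclass(frozen=True)
class MosaicLayout:
    """Per-tile pixel offsets on a shared canvas."""

    offsets: dict[tuple[int, int], tuple[int, int]]  # tile_index → (row, col)
    canvas_shape_px: tuple[int, int]
    pixel_size_um: float


def _tile_fields(tile) -> tuple[np.ndarray, AcquisitionMetadata | dict]:
    """Accept ReconstructedTile or LayerEntry-like objects."""
    if isinstance(tile, ReconstructedTile):
        return tile.image, tile.metadata
    if isinstance(tile, LayerEntry):
        meta = tile.metadata.get("acquisition", tile.metadata)
        return tile.image, AcquisitionMetadata.from_json(json.dumps(meta))
    raise TypeError(f"cannot interpret tile of type {type(tile).__name__}")


def _as_tiles(tiles) -> list[ReconstructedTile]:
    out = []
    for t in tiles:
        img, meta = _tile_fields(t)
        if isinstance(t, ReconstructedTile):
            out.append(t)
        else:
            out.append(ReconstructedTile(image=img, source_raw=None, metadata=meta,
                                         recon=ReconParams()))
    return out


def compute_layout(tiles) -> MosaicLayout:
    """Nominal stage-offset placement.

    ``offset(i,j) = round((stage_xy(i,j) − min stage_xy) / pixel_size)``,
    stage x → columns, stage y → rows; the canvas is sized to contain
    every tile.  All tiles must share pixel size and shape.
    """
    tiles = _as_tiles(tiles)
    if not tiles:
        raise ValueError("no tiles")
    px = tiles[0].metadata.pixel_size_um
    shape = tiles[0].image.shape
    for t in tiles[1:]:
        if abs(t.metadata.pixel_size_um - px) > 1e-9:
            raise ValueError("tiles have mixed pixel sizes")
        if t.image.shape != shape:
            raise ValueError("tiles have mixed shapes")
    xs = [t.metadata.stage_position_um[0] for t in tiles]
    ys = [t.metadata.stage_position_um[1] for t in tiles]
    x_min, y_min = min(xs), min(ys)
    offsets: dict[tuple[int, int], tuple[int, int]] = {}
    for t, x, y in zip(tiles, xs, ys):
        idx = tuple(t.metadata.tile_index) if t.metadata.tile_index is not None else (0, len(offsets))
        offsets[idx] = (int(round((y - y_min) / px)), int(round((x - x_min) / px)))
    h = max(r for r, _ in offsets.values()) + shape[0]
    w = max(c for _, c in offsets.values()) + shape[1]
    return MosaicLayout(offsets=offsets, canvas_shape_px=(h, w), pixel_size_um=px)


def _tile_offset(tile: ReconstructedTile, layout: MosaicLayout, fallback: int) -> tuple[int, int]:
    idx = tuple(tile.metadata.tile_index) if tile.metadata.tile_index is not None else (0, fallback)
    try:
        return layout.offsets[idx]
    except KeyError:
        raise ValueError(f"layout has no offset for tile {idx}") from None


def assemble_mosaic(tiles, layout: MosaicLayout, blend: str = "average") -> np.ndarray:
    """Compose tiles onto the canvas.

    ``overwrite`` — later tiles win in overlaps; ``average`` — per-pixel
    mean over covering tiles; ``feather`` — distance-to-edge weighted
    mean (smooths seams when tiles disagree).  Uncovered pixels are 0.
    """
    if blend not in ("overwrite", "average", "feather"):
        raise ValueError(f"unknown blend mode {blend!r}")
    tiles = _as_tiles(tiles)
    H, W = layout.canvas_shape_px
    canvas = np.zeros((H, W), dtype=np.float64)
    weight = np.zeros((H, W), dtype=np.float64)
    for fallback, t in enumerate(tiles):
        r0, c0 = _tile_offset(t, layout, fallback)
        th, tw = t.image.shape
        if r0 < 0 or c0 < 0 or r0 + th > H or c0 + tw > W:
            raise ValueError(f"tile at offset {(r0, c0)} exceeds canvas {layout.canvas_shape_px}")
        img = t.image.astype(np.float64)
        if blend == "overwrite":
            canvas[r0 : r0 + th, c0 : c0 + tw] = img
            weight[r0 : r0 + th, c0 : c0 + tw] = 1.0
        elif blend == "average":
            canvas[r0 : r0 + th, c0 : c0 + tw] += img
            weight[r0 : r0 + th, c0 : c0 + tw] += 1.0
        else:  # feather
            ry = np.minimum(np.arange(th) + 1, np.arange(th)[::-1] + 1)
            rx = np.minimum(np.arange(tw) + 1, np.arange(tw)[::-1] + 1)
            wmap = np.minimum.outer(ry, rx).astype(np.float64)
            canvas[r0 : r0 + th, c0 : c0 + tw] += img * wmap
            weight[r0 : r0 + th, c0 : c0 + tw] += wmap
    if blend == "overwrite":
        return canvas
    out = np.zeros_like(canvas)
    covered = weight > 0
    out[covered] = canvas[covered] / weight[covered]
    return out


def overlap_consistency(tiles, layout: MosaicLayout) -> dict[tuple, float]:
    """RMS pixel difference over every overlapping tile pair.

    Keys are (tile_index_a, tile_index_b) pairs; pairs without overlap
    are omitted.  Zero for perfectly consistent tiles; ≈ σ·√2 when the
    tiles carry independent additive noise of standard deviation σ.
    """
    tiles = _as_tiles(tiles)
    placed = []
    for fallback, t in enumerate(tiles):
        idx = tuple(t.metadata.tile_index) if t.metadata.tile_index is not None else (0, fallback)
        r0, c0 = layout.offsets[idx]
        placed.append((idx, r0, c0, t.image.astype(np.float64)))
    out: dict[tuple, float] = {}
    for a in range(len(placed)):
        ia, ra, ca, img_a = placed[a]
        ha, wa = img_a.shape
        for b in range(a + 1, len(placed)):
            ib, rb, cb, img_b = placed[b]
            hb, wb = img_b.shape
            r0 = max(ra, rb)
            r1 = min(ra + ha, rb + hb)
            c0 = max(ca, cb)
            c1 = min(ca + wa, cb + wb)
            if r0 >= r1 or c0 >= c1:
                continue
            sub_a = img_a[r0 - ra : r1 - ra, c0 - ca : c1 - ca]
            sub_b = img_b[r0 - rb : r1 - rb, c0 - cb : c1 - cb]
            out[(ia, ib)] = float(np.sqrt(np.mean((sub_a - sub_b) ** 2)))
    return out


class ViewerUnit:
    """Watches the ``rec`` folder and registers arriving tiles as layers."""

    def __init__(self, watch_config, registry: LayerRegistry | None = None) -> None:
        from scopeflow.filewatch import WatchSession

        self.registry = registry if registry is not None else LayerRegistry()
        self.session = WatchSession(watch_config, item_handler=self._handle, role="orchestrator")

    def _handle(self, path: Path) -> None:
        register_layer(self.registry, path)

    def start(self) -> "ViewerUnit":
        self.session.start()
        return self

    def stop_and_join(self, timeout: float | None = None) -> None:
        self.session.stop_and_join(timeout)

    @property
    def log(self):
        return self.session.log

    @property
    def idle(self) -> bool:
        return self.session.idle
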
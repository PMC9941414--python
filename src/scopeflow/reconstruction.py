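"""Reconstruction unit: n-frame raw stacks → one image, TIFF + OME-Zarr out.

The unit watches the acquisition data folder, reconstructs every arriving
stack, and writes the result twice — a single-page 32-bit-float TIFF (the
metadata as an ImageDescription JSON) and an OME-NGFF 0.4 single-scale
Zarr — into the ``rec`` subfolder of the data folder, the framework's
convention for chaining units downstream.

The default algorithm is focus reassignment: in frame ``k`` each focus
pixel collects the signal of its own illumination spot, so the
reconstructed value at a focus position is the (2w+1)²-window sum of the
background-subtracted frame around it.  With pitch == steps and w = 0
this exactly inverts the simulator's forward model, which is how the
pipeline is validated end-to-end.  The stage is pluggable via
``algorithm_id`` so a different stack→image transform can be registered.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Callable

import numpy as np
import tifffile
import zarr

from scopeflow.acquisition import AcquisitionMetadata, load_raw
from scopeflow.filewatch import WatchConfig, WatchSession
from scopeflow.simulator import RawStack

__all__ = [
    "ReconParams",
    "ReconstructedTile",
    "reconstruct_stack",
    "process_raw_file",
    "run_reconstruction_unit",
    "register_algorithm",
    "write_ome_zarr",
    "read_ome_zarr",
    "RECON_ATTR",
]

logger = logging.getLogger(__name__)

RECON_ATTR = "ImSwitchData"
_ALGORITHMS: dict[str, Callable[[RawStack, "ReconParams"], np.ndarray]] = {}


def register_algorithm(algorithm_id: str):
    """Decorator registering a stack→image transform under an id."""

    def deco(fn):
        _ALGORITHMS[algorithm_id] = fn
        return fn

    return deco


@dataclass(frozen=True)
class ReconParams:
    """Reconstruction settings.

    ``window_halfwidth_px`` (w) sets the per-focus collection window
    (2w+1)²; it must stay below half the foci pitch or windows of
    neighboring foci would overlap.  ``background_mode`` subtracts
    nothing (``none``) or the stack's global minimum (``global_min``).
    """

    window_halfwidth_px: int = 0
    background_mode: str = "none"  # none | global_min
    algorithm_id: str = "focus_reassignment"

    def __post_init__(self) -> None:
        if self.window_halfwidth_px < 0:
            raise ValueError("window_halfwidth_px must be >= 0")
        if self.background_mode not in ("none", "global_min"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReconstructedTile:
    """One reconstructed image with its provenance."""

    image: np.ndarray
    source_raw: Path | None
    metadata: AcquisitionMetadata
    recon: ReconParams = field(default_factory=ReconParams)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.shape != tuple(self.metadata.detector_shape_px):
            raise ValueError("reconstructed image shape must equal the detector shape")


@register_algorithm("focus_reassignment")
def _focus_reassignment(stack: RawStack, params: ReconParams) -> np.ndarray:
    s = stack.scan.steps_per_axis
    p = stack.scan.foci_pitch_px
    w = params.window_halfwidth_px
    if 2 * w >= p:
        raise ValueError(
            f"window halfwidth {w} overlaps neighboring foci at pitch {p} (need w < pitch/2)"
        )
    frames = stack.frames.astype(np.float64)
    b = float(frames.min()) if params.background_mode == "global_min" else 0.0
    H, W = stack.frame_shape
    out = np.zeros((H, W), dtype=np.float64)
    for k in range(stack.n_frames):
        ky, kx = divmod(k, s)
        fk = frames[k] - b
        if w == 0:
            out[ky::p, kx::p] = fk[ky::p, kx::p]
            continue
        rows = np.arange(ky, H, p)
        cols = np.arange(kx, W, p)
        acc = np.zeros((rows.size, cols.size), dtype=np.float64)
        for dy in range(-w, w + 1):
            rr = rows + dy
            rvalid = (rr >= 0) & (rr < H)
            for dx in range(-w, w + 1):
                cc = cols + dx
                cvalid = (cc >= 0) & (cc < W)
                sub = fk[np.ix_(rr[rvalid], cc[cvalid])]
                acc[np.ix_(rvalid, cvalid)] += sub
        out[np.ix_(rows, cols)] = acc
    return out


def reconstruct_stack(stack: RawStack, params: ReconParams | None = None) -> np.ndarray:
    """Reconstruct one raw stack into a single 2D float image.

    Dispatches on ``params.algorithm_id``; the default focus-reassignment
    transform assigns, for every frame, the windowed background-subtracted
    signal at each of that frame's focus positions.  Pixels that are a
    focus in no frame (pitch > steps) stay 0.
    """
    params = params or ReconParams()
    try:
        algorithm = _ALGORITHMS[params.algorithm_id]
    except KeyError:
        raise ValueError(
            f"unknown algorithm_id {params.algorithm_id!r}; registered: {sorted(_ALGORITHMS)}"
        ) from None
    return algorithm(stack, params)


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


def write_ome_zarr(image: np.ndarray, attrs_json: str, path: Path, pixel_size_um: float) -> None:
    """Single-scale OME-NGFF 0.4 store: group with multiscales metadata and
    the image under dataset ``0``."""
    path = Path(path)
    group = zarr.open_group(str(path), mode="w", zarr_format=2)
    group.attrs["multiscales"] = [
        {
            "version": "0.4",
            "name": path.stem,
            "axes": [
                {"name": "y", "type": "space", "unit": "micrometer"},
                {"name": "x", "type": "space", "unit": "micrometer"},
            ],
            "datasets": [
                {
                    "path": "0",
                    "coordinateTransformations": [
                        {"type": "scale", "scale": [pixel_size_um, pixel_size_um]}
                    ],
                }
            ],
        }
    ]
    group.attrs[RECON_ATTR] = attrs_json
    arr = group.create_array("0", shape=image.shape, dtype="float32")
    arr[:] = image.astype(np.float32)


def read_ome_zarr(path: Path) -> tuple[np.ndarray, str | None]:
    """Read back a single-scale OME-Zarr; returns (image, metadata JSON)."""
    group = zarr.open_group(str(path), mode="r")
    image = np.asarray(group["0"][:])
    attrs = group.attrs.get(RECON_ATTR)
    return image, attrs


def _combined_attrs(meta: AcquisitionMetadata, params: ReconParams) -> str:
    return json.dumps({"acquisition": json.loads(meta.to_json()), "recon": params.to_dict()})


def process_raw_file(
    path: Path,
    params: ReconParams | None = None,
    rec_root: Path | None = None,
) -> tuple[Path, Path]:
    """Reconstruct one raw file and write TIFF + OME-Zarr under ``rec_root``.

    Outputs are written to temporary names and renamed on success, so
    downstream watchers never observe half-written files; on failure no
    partial output is left behind.
    """
    params = params or ReconParams()
    path = Path(path)
    if rec_root is None:
        rec_root = path.parent / "rec"
    rec_root = Path(rec_root)
    rec_root.mkdir(parents=True, exist_ok=True)
    stem = path.name
    for ext in (".zarr", ".h5", ".hdf5"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    tiff_path = rec_root / f"{stem}_rec.tiff"
    zarr_path = rec_root / f"{stem}_rec.zarr"
    tiff_tmp = rec_root / f"{stem}_rec.tiff.part"
    zarr_tmp = rec_root / f"{stem}_rec.zarr.part"
    try:
        stack, meta = load_raw(path)
        image = reconstruct_stack(stack, params).astype(np.float32)
        attrs = _combined_attrs(meta, params)
        tifffile.imwrite(tiff_tmp, image, description=attrs)
        write_ome_zarr(image, attrs, zarr_tmp, meta.pixel_size_um)
        tiff_tmp.rename(tiff_path)
        zarr_tmp.rename(zarr_path)
    except Exception:
        if tiff_tmp.exists():
            tiff_tmp.unlink()
        if zarr_tmp.exists():
            shutil.rmtree(zarr_tmp, ignore_errors=True)
        raise
    return tiff_path, zarr_path


class ReconstructionUnit:
    """Watches the data folder and reconstructs each arriving raw stack."""

    def __init__(
        self,
        watch: WatchConfig,
        params: ReconParams | None = None,
        rec_root: Path | None = None,
        on_file_reconstructed=None,
    ) -> None:
        self.params = params or ReconParams()
        # rec/ lives inside the data folder but is never watched: the
        # watcher lists only top-level entries and outputs are .tiff/.zarr
        # under rec/, so no self-feedback loop can form
        self.rec_root = Path(rec_root) if rec_root else Path(watch.folder) / "rec"
        self.on_file_reconstructed = on_file_reconstructed
        self.outputs: list[tuple[Path, Path]] = []
        self.session = WatchSession(watch, item_handler=self._handle, role="reconstruction")

    def _handle(self, path: Path) -> None:
        pair = process_raw_file(path, self.params, self.rec_root)
        self.outputs.append(pair)
        if self.on_file_reconstructed is not None:
            self.on_file_reconstructed(pair)

    def start(self) -> "ReconstructionUnit":
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


def run_reconstruction_unit(
    watch: WatchConfig,
    params: ReconParams | None = None,
    rec_root: Path | None = None,
    on_file_reconstructed=None,
) -> ReconstructionUnit:
    """Start the reconstruction unit; returns the running unit handle."""
    return ReconstructionUnit(watch, params, rec_root, on_file_reconstructed).start()
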
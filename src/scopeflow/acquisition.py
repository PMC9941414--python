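"""Acquisition unit: experiment-script execution and raw-stack I/O.

The unit watches a scripts folder, runs each arriving script FIFO in a
restricted namespace that exposes only the exported control API
(``api.imcontrol.*``), and writes each scan's raw stack plus metadata to
Zarr or HDF5.  Metadata travels with the data as a single JSON attribute
named ``ImSwitchData`` so downstream units need no side channel.

The device backend here is the bundled :class:`Microscope` simulator
(virtual sample + stage + grid-scan camera); the API surface is the same
one a hardware backend would export.
"""

from __future__ import annotations

import json
import logging
import threading
import time
import traceback
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import h5py
import numpy as np
import zarr

from scopeflow._version import __version__ as _pkg_version
from scopeflow.filewatch import WatchConfig, WatchSession
from scopeflow.simulator import RawStack, ScanConfig, VirtualSample, acquire_stack, stack_duration_s

__all__ = [
    "ScriptJob",
    "AcquisitionMetadata",
    "Microscope",
    "ControlAPI",
    "run_script",
    "save_raw",
    "load_raw",
    "run_acquisition_unit",
    "METADATA_ATTR",
]

logger = logging.getLogger(__name__)

METADATA_ATTR = "ImSwitchData"
RAW_EXTENSIONS = {"zarr": ".zarr", "hdf5": ".h5"}


@dataclass
class ScriptJob:
    """One queued experiment script."""

    script_path: Path
    enqueued_at: datetime = field(default_factory=datetime.now)
    status: str = "queued"  # queued → running → ok | failed
    error: str | None = None

    _TRANSITIONS = {"queued": {"running"}, "running": {"ok", "failed"}}

    def transition(self, new_status: str) -> None:
        if new_status not in self._TRANSITIONS.get(self.status, set()):
            raise ValueError(f"illegal status transition {self.status} → {new_status}")
        self.status = new_status


@dataclass
class AcquisitionMetadata:
    """Experimental context stored alongside every raw stack."""

    stage_position_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tile_index: tuple[int, int] | None = None
    lapse_index: int | None = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    detector_shape_px: tuple[int, int] = (64, 64)
    pixel_size_um: float = 1.0
    laser_settings: dict[str, float] = field(default_factory=dict)
    acquired_at: str = ""
    writer_version: str = _pkg_version

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["scan"] = self.scan.to_dict()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionMetadata":
        d = json.loads(text)
        d["scan"] = ScanConfig.from_dict(d["scan"])
        d["stage_position_um"] = tuple(d["stage_position_um"])
        if d.get("tile_index") is not None:
            d["tile_index"] = tuple(d["tile_index"])
        d["detector_shape_px"] = tuple(d["detector_shape_px"])
        return cls(**d)


# ---------------------------------------------------------------------------
# raw-stack I/O
# ---------------------------------------------------------------------------


def save_raw(
    stack: RawStack,
    meta: AcquisitionMetadata,
    folder: Path,
    fmt: str = "zarr",
    stem: str | None = None,
) -> Path:
    """Write one raw stack with its metadata attribute.

    Zarr: a v2 directory store with the array at the root, chunked one
    frame per chunk (directory-tree chunking suits shared-filesystem
    watchers).  HDF5: a single ``data`` dataset.  Both carry the metadata
    JSON under the ``ImSwitchData`` attribute.  Data are stored as
    n_frames×H×W uint16.
    """
    if fmt not in RAW_EXTENSIONS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {sorted(RAW_EXTENSIONS)}")
    if stack.n_frames == 0:
        raise ValueError("refusing to write a 0-frame stack")
    if tuple(meta.detector_shape_px) != stack.frame_shape:
        raise ValueError("metadata detector_shape_px does not match the stack frames")
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = f"raw_{datetime.now().strftime('%Y%m%dT%H%M%S.%f')}"
    ext = RAW_EXTENSIONS[fmt]
    path = folder / f"{stem}{ext}"
    k = 1
    while path.exists():
        path = folder / f"{stem}_{k}{ext}"
        k += 1
    data = np.ascontiguousarray(stack.frames, dtype=np.uint16)
    if fmt == "zarr":
        # write under a temp name, rename when complete: watchers on the
        # data folder must never pick up a half-written store
        tmp = path.with_name(path.name + ".part")
        arr = zarr.create_array(
            store=str(tmp),
            shape=data.shape,
            chunks=(1, *stack.frame_shape),
            dtype="uint16",
            zarr_format=2,
        )
        arr[:] = data
        arr.attrs[METADATA_ATTR] = meta.to_json()
        tmp.rename(path)
    else:
        tmp = path.with_name(path.name + ".part")
        with h5py.File(tmp, "w") as f:
            dset = f.create_dataset("data", data=data)
            dset.attrs[METADATA_ATTR] = meta.to_json()
            f.attrs[METADATA_ATTR] = meta.to_json()
        tmp.rename(path)
    return path


def load_raw(path: Path) -> tuple[RawStack, AcquisitionMetadata]:
    """Load a raw stack written by :func:`save_raw` (either format)."""
    path = Path(path)
    if path.is_dir():  # zarr store
        arr = zarr.open_array(str(path), mode="r")
        if METADATA_ATTR not in arr.attrs:
            raise ValueError(f"{path}: missing {METADATA_ATTR} attribute")
        meta = AcquisitionMetadata.from_json(arr.attrs[METADATA_ATTR])
        frames = np.asarray(arr[:])
    else:
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise ValueError(f"{path}: missing 'data' dataset")
            dset = f["data"]
            if METADATA_ATTR not in dset.attrs:
                raise ValueError(f"{path}: missing {METADATA_ATTR} attribute")
            meta = AcquisitionMetadata.from_json(dset.attrs[METADATA_ATTR])
            frames = dset[:]
    return RawStack(frames=frames, scan=meta.scan), meta


# ---------------------------------------------------------------------------
# device backend (simulator-backed microscope)
# ---------------------------------------------------------------------------


class Microscope:
    """Simulated instrument state behind the control API.

    Holds the virtual sample, the stage position, the recording folder /
    save format, the scan configuration and free-form parameters.  A scan
    takes real time (n_frames × frame_period, scaled by ``time_scale``)
    and writes exactly one raw file.
    """

    def __init__(
        self,
        sample: VirtualSample,
        scan: ScanConfig | None = None,
        fov_px: tuple[int, int] = (64, 64),
        recording_folder: Path | None = None,
        save_format: str = "zarr",
        seed: int = 0,
        time_scale: float = 1.0,
    ) -> None:
        self.sample = sample
        self.scan = scan or ScanConfig()
        self.fov_px = tuple(fov_px)
        self.recording_folder = Path(recording_folder) if recording_folder else None
        self.save_format = save_format
        self.seed = seed
        self.time_scale = time_scale
        self.stage_um = [0.0, 0.0, 0.0]
        self.params: dict[str, object] = {}
        self.tile_plan: list[dict] = []
        self.laser_settings: dict[str, float] = {}
        self.written_files: list[Path] = []
        self._scan_lock = threading.Lock()
        self._acq_index = 0
        self._scan_running = threading.Event()

    # stage -----------------------------------------------------------------
    def move_stage(self, x: float | None = None, y: float | None = None, z: float | None = None) -> None:
        if x is not None:
            self.stage_um[0] = float(x)
        if y is not None:
            self.stage_um[1] = float(y)
        if z is not None:
            self.stage_um[2] = float(z)

    def get_stage_position(self) -> tuple[float, float, float]:
        return tuple(self.stage_um)

    # scanning --------------------------------------------------------------
    def run_scan(
        self,
        tag: str = "scan",
        tile: tuple[int, int] | None = None,
        lapse: int | None = None,
    ) -> str:
        """Acquire one stack at the current position and save it.

        Synchronous: returns only after the raw file is fully written.
        Scripts are serial, so the lock only guards against API misuse.
        """
        if self.recording_folder is None:
            raise RuntimeError("recording folder not set")
        with self._scan_lock:
            if self._scan_running.is_set():
                raise RuntimeError("scan already running")
            self._scan_running.set()
            try:
                duration = stack_duration_s(self.scan) * self.time_scale
                if duration > 0:
                    time.sleep(duration)
                # per-acquisition RNG stream: deterministic regardless of
                # wall-clock timing or which unit thread runs first
                rng = np.random.default_rng([self.seed, self._acq_index])
                stack = acquire_stack(
                    self.sample,
                    (self.stage_um[0], self.stage_um[1]),
                    self.scan,
                    fov_px=self.fov_px,
                    rng=rng,
                )
                meta = AcquisitionMetadata(
                    stage_position_um=tuple(self.stage_um),
                    tile_index=tile,
                    lapse_index=lapse,
                    scan=self.scan,
                    detector_shape_px=self.fov_px,
                    pixel_size_um=self.sample.pixel_size_um,
                    laser_settings=dict(self.laser_settings),
                    acquired_at=datetime.now().isoformat(timespec="milliseconds"),
                )
                stem = tag
                if lapse is not None:
                    stem += f"_t{lapse:03d}"
                if tile is not None:
                    stem += f"_x{tile[0]:02d}_y{tile[1]:02d}"
                stem += f"_{self._acq_index:05d}"
                path = save_raw(stack, meta, self.recording_folder, self.save_format, stem=stem)
                self._acq_index += 1
                self.written_files.append(path)
                return str(path)
            finally:
                self._scan_running.clear()

    @property
    def n_acquisitions(self) -> int:
        return self._acq_index

    def wait_for_scan_end(self) -> None:
        while self._scan_running.is_set():
            time.sleep(0.001)

    # configuration ---------------------------------------------------------
    def set_recording_folder(self, folder: str) -> None:
        self.recording_folder = Path(folder)
        self.recording_folder.mkdir(parents=True, exist_ok=True)

    def set_save_format(self, fmt: str) -> None:
        if fmt not in RAW_EXTENSIONS:
            raise ValueError(f"unsupported format {fmt!r}")
        self.save_format = fmt

    def set_param(self, name: str, value) -> None:
        self.params[name] = value

    def get_param(self, name: str, default=None):
        return self.params.get(name, default)


class _APINamespace:
    """The ``api.imcontrol`` callables visible to scripts."""

    def __init__(self, scope: Microscope, log_fn) -> None:
        self.move_stage = scope.move_stage
        self.get_stage_position = scope.get_stage_position
        self.run_scan = scope.run_scan
        self.set_recording_folder = scope.set_recording_folder
        self.set_save_format = scope.set_save_format
        self.wait_for_scan_end = scope.wait_for_scan_end
        self.set_param = scope.set_param
        self.get_param = scope.get_param
        self.log_message = log_fn
        self._scope = scope

    def get_tile_plan(self) -> list[dict]:
        """Per-tile stage targets configured for this experiment (list of
        dicts with tile_index, x_um, y_um, z_um, skip)."""
        return [dict(t) for t in self._scope.tile_plan]

    def wait(self, seconds: float) -> None:
        """Settle time, e.g. after a stage move."""
        if seconds > 0:
            time.sleep(seconds * self._scope.time_scale)


class ControlAPI:
    """The object injected into scripts as ``api``.

    Mirrors the exported-API pattern: every microscope-control call lives
    under ``api.imcontrol``; all calls are synchronous from the script's
    point of view.
    """

    def __init__(self, scope: Microscope) -> None:
        self.scope = scope
        self.messages: list[str] = []
        self.imcontrol = _APINamespace(scope, self._log_message)

    def _log_message(self, msg: str) -> None:
        self.messages.append(str(msg))
        logger.info("script: %s", msg)


_SCRIPT_BUILTINS = {
    "range": range,
    "len": len,
    "enumerate": enumerate,
    "zip": zip,
    "int": int,
    "float": float,
    "bool": bool,
    "str": str,
    "list": list,
    "dict": dict,
    "tuple": tuple,
    "min": min,
    "max": max,
    "abs": abs,
    "round": round,
    "sum": sum,
    "sorted": sorted,
    "print": print,
    "True": True,
    "False": False,
    "None": None,
}


def run_script(job: ScriptJob, api: ControlAPI) -> str:
    """Execute one experiment script in the restricted API namespace.

    Only ``api`` plus a short list of safe builtins is visible — no
    imports, no file or network primitives.  Exceptions mark the job
    failed (with traceback retained) and never propagate, so the queue
    proceeds to the next job.
    """
    job.transition("running")
    source = Path(job.script_path).read_text(encoding="utf-8")
    namespace = {"__builtins__": dict(_SCRIPT_BUILTINS), "api": api}
    try:
        exec(compile(source, str(job.script_path), "exec"), namespace)
    except Exception:
        job.error = traceback.format_exc()
        logger.error("script %s failed:\n%s", job.script_path, job.error)
        job.transition("failed")
        return job.status
    job.transition("ok")
    return job.status


class AcquisitionUnit:
    """Watches a scripts folder and executes arriving scripts FIFO.

    Wraps a :class:`~scopeflow.filewatch.WatchSession` with role
    ``acquisition``; each delivered ``.py`` file becomes a
    :class:`ScriptJob`.  A script-finished callback fires after every
    script regardless of outcome (the hook tests and the demo use to
    track progress).
    """

    def __init__(
        self,
        scripts_dir: Path,
        scope: Microscope,
        poll_interval_s: float = 1.0,
        on_script_finished=None,
    ) -> None:
        self.scope = scope
        self.jobs: list[ScriptJob] = []
        self.on_script_finished = on_script_finished
        config = WatchConfig(
            folder=Path(scripts_dir),
            extensions=(".py",),
            poll_interval_s=poll_interval_s,
        )
        self.session = WatchSession(config, item_handler=self._handle, role="acquisition")

    def _handle(self, path: Path) -> None:
        job = ScriptJob(script_path=path)
        self.jobs.append(job)
        api = ControlAPI(self.scope)
        status = run_script(job, api)
        if self.on_script_finished is not None:
            self.on_script_finished(job)
        if status == "failed":
            raise RuntimeError(f"script failed: {path}")

    def start(self) -> "AcquisitionUnit":
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


def run_acquisition_unit(
    scripts_dir: Path,
    scope: Microscope,
    poll_interval_s: float = 1.0,
    on_script_finished=None,
) -> AcquisitionUnit:
    """Start the acquisition unit; returns the running unit handle."""
    return AcquisitionUnit(scripts_dir, scope, poll_interval_s, on_script_finished).start()
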
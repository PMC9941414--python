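"""Single-machine end-to-end demo: three units over one shared folder.

Launches the acquisition, reconstruction and viewer units as concurrent
watch sessions inside one process (units coupled only through the shared
folder tree, exactly as they would be across machines), submits a bundled
experiment script, waits for quiescence, assembles the mosaic and writes
the logs.

Quiescence has to be inferred — the filesystem is the units' only
channel, so there is no termination signal: the demo declares the run
finished when the submitted script has completed, every queue is idle,
item counts are conserved through the pipeline (raw files ==
reconstructions == registered layers) and no unit has seen activity for
two poll intervals.
"""

from __future__ import annotations

import importlib.resources
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from scopeflow.acquisition import Microscope, run_acquisition_unit
from scopeflow.config import FrameworkConfig
from scopeflow.filewatch import ExperimentLog, WatchConfig, latency_summary, write_log
from scopeflow.orchestrator import (
    LayerRegistry,
    ViewerUnit,
    assemble_mosaic,
    compute_layout,
)
from scopeflow.planner import TilePlan, plan_grid
from scopeflow.reconstruction import ReconParams, run_reconstruction_unit
from scopeflow.simulator import ScanConfig, VirtualSample, make_sample

__all__ = ["DemoResult", "DemoTimeout", "run_demo", "bundled_script"]

EXPERIMENTS = ("tiling", "timelapse")


class DemoTimeout(RuntimeError):
    """The pipeline did not reach quiescence within the allowed time."""


@dataclass
class DemoResult:
    experiment: str
    n_expected: int
    raw_files: list[Path]
    recon_outputs: list[tuple[Path, Path]]
    registry: LayerRegistry
    mosaic: np.ndarray
    mosaic_path: Path
    sample: VirtualSample
    plan: TilePlan
    logs: dict[str, ExperimentLog]
    log_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def n_raw(self) -> int:
        return len(self.raw_files)

    @property
    def n_reconstructed(self) -> int:
        return len(self.recon_outputs)

    @property
    def n_registered(self) -> int:
        return len(self.registry)

    def ground_truth_crop(self) -> np.ndarray:
        """The sample region the mosaic canvas covers (noiseless identity
        reference: with unit amplitude and zero background the averaged
        mosaic equals this crop exactly)."""
        layout = compute_layout(self.registry.entries)
        px = layout.pixel_size_um
        xs = [e.metadata["acquisition"]["stage_position_um"][0] for e in self.registry.entries]
        ys = [e.metadata["acquisition"]["stage_position_um"][1] for e in self.registry.entries]
        c0 = int(round(min(xs) / px))
        r0 = int(round(min(ys) / px))
        H, W = layout.canvas_shape_px
        return self.sample.image[r0 : r0 + H, c0 : c0 + W]

    def summary(self) -> str:
        rec_stats = latency_summary(self.logs["reconstruction"])
        mean = rec_stats["mean_s"]
        return (
            f"experiment: {self.experiment}\n"
            f"tiles acquired: {self.n_raw}\n"
            f"tiles reconstructed: {self.n_reconstructed}\n"
            f"layers registered: {self.n_registered}\n"
            f"mosaic: {self.mosaic.shape[0]}x{self.mosaic.shape[1]} px -> {self.mosaic_path}\n"
            f"mean reconstruction latency: "
            + (f"{mean:.3f} s" if mean is not None else "n/a")
        )


def bundled_script(experiment: str) -> str:
    """Source text of a bundled demo experiment script."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")
    return (
        importlib.resources.files("scopeflow")
        .joinpath("demo_scripts", f"{experiment}.py")
        .read_text(encoding="utf-8")
    )


def _demo_plan(config: FrameworkConfig, experiment: str) -> TilePlan:
    if experiment == "tiling":
        nx, ny = config.tiles_nx, config.tiles_ny
    else:
        nx, ny = 2, 2
    if nx < 1 or ny < 1:
        raise ValueError("demo grid must be at least 1x1")
    return plan_grid(nx, ny, config.fov_um, config.overlap_frac)


def _demo_sample(config: FrameworkConfig, plan: TilePlan) -> VirtualSample:
    extent_px = int(np.ceil(
        max(plan.nx, plan.ny) * plan.step_um / config.pixel_size_um
    )) + config.fov_px
    size = max(extent_px + 16, 2 * config.fov_px)
    return make_sample(
        config.sample_kind, size, seed=config.seed, pixel_size_um=config.pixel_size_um
    )


def run_demo(
    config: FrameworkConfig,
    experiment: str = "tiling",
    timeout_s: float = 240.0,
    blend: str = "average",
) -> DemoResult:
    """Run one bundled experiment end-to-end; returns counts, logs and the
    assembled mosaic.  Raises :class:`DemoTimeout` if the pipeline never
    goes quiet."""
    config = config.resolved()
    plan = _demo_plan(config, experiment)
    sample = _demo_sample(config, plan)
    scan = ScanConfig(
        steps_per_axis=config.steps_per_axis,
        foci_pitch_px=config.foci_pitch_px,
        frame_period_ms=config.frame_period_ms,
        amplitude=config.amplitude,
        background=config.background,
        noise=config.noise,
    )
    scope = Microscope(
        sample,
        scan=scan,
        fov_px=(config.fov_px, config.fov_px),
        recording_folder=config.data_dir,
        save_format=config.raw_format,
        seed=config.seed,
    )
    scope.tile_plan = [t.to_dict() for t in plan.targets]
    scope.set_param("settle_s", config.settle_s)
    scope.set_param("n_lapses", config.n_lapses)
    n_tiles = len(plan.active_targets)
    n_expected = n_tiles * (config.n_lapses if experiment == "timelapse" else 1)

    poll = config.poll_interval_s
    acq = run_acquisition_unit(config.scripts_dir, scope, poll_interval_s=poll)
    recon = run_reconstruction_unit(
        WatchConfig(folder=config.data_dir, extensions=(".zarr", ".h5", ".hdf5"),
                    poll_interval_s=poll),
        params=ReconParams(
            window_halfwidth_px=config.window_halfwidth_px,
            background_mode=config.background_mode,
        ),
        rec_root=config.rec_dir,
    )
    viewer = ViewerUnit(
        WatchConfig(folder=config.rec_dir, extensions=(".tiff",), poll_interval_s=poll)
    ).start()
    units = (acq.session, recon.session, viewer.session)

    try:
        # submit the experiment: write the bundled script into scripts/
        # (write-then-rename so the watcher can't pick up a partial file)
        script_tmp = config.scripts_dir / f"{experiment}.py.part"
        script_tmp.write_text(bundled_script(experiment), encoding="utf-8")
        script_tmp.rename(config.scripts_dir / f"{experiment}.py")

        deadline = time.monotonic() + timeout_s
        while True:
            script_done = bool(acq.jobs) and all(
                j.status in ("ok", "failed") for j in acq.jobs
            )
            counts_conserved = (
                scope.n_acquisitions == n_expected
                and len(recon.outputs) == scope.n_acquisitions
                and len(viewer.registry) == len(recon.outputs)
            )
            quiet_since = time.monotonic() - max(u.last_activity for u in units)
            if (
                script_done
                and counts_conserved
                and all(u.idle for u in units)
                and quiet_since > 2 * poll
            ):
                break
            if time.monotonic() > deadline:
                raise DemoTimeout(
                    f"no quiescence after {timeout_s:.0f} s: "
                    f"scripts={len(acq.jobs)} raw={scope.n_acquisitions}/{n_expected} "
                    f"rec={len(recon.outputs)} layers={len(viewer.registry)}"
                )
            time.sleep(min(poll, 0.05))
    finally:
        for unit in (acq, recon, viewer):
            unit.stop_and_join(timeout=10)

    logs = {"acquisition": acq.log, "reconstruction": recon.log, "orchestrator": viewer.log}
    log_paths = {role: write_log(log, config.shared_root) for role, log in logs.items()}

    layout = compute_layout(viewer.registry.entries)
    mosaic = assemble_mosaic(viewer.registry.entries, layout, blend=blend)
    mosaic_path = config.shared_root / f"mosaic_{experiment}.tiff"
    tifffile.imwrite(mosaic_path, mosaic.astype(np.float32))

    return DemoResult(
        experiment=experiment,
        n_expected=n_expected,
        raw_files=list(scope.written_files),
        recon_outputs=list(recon.outputs),
        registry=viewer.registry,
        mosaic=mosaic,
        mosaic_path=mosaic_path,
        sample=sample,
        plan=plan,
        logs=logs,
        log_paths=log_paths,
    )
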
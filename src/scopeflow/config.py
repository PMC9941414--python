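"""Framework configuration: the shared folder tree and unit settings.

All units are wired through one ``shared_root``: scripts arrive in
``scripts/``, raw stacks in ``data/``, reconstructions in ``data/rec/``
(the ``rec`` subfolder convention ties acquisition, reconstruction and
viewing together without any channel besides the filesystem).  A config
file is YAML key/value; every CLI flag overrides its config key.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = ["FrameworkConfig", "load_config"]


@dataclass(frozen=True)
class FrameworkConfig:
    shared_root: Path = Path("scopeflow_run")
    scripts_dir: Path | None = None  # default <shared_root>/scripts
    data_dir: Path | None = None  # default <shared_root>/data
    rec_dir: Path | None = None  # default <data_dir>/rec
    poll_interval_s: float = 1.0
    raw_format: str = "zarr"  # zarr | hdf5

    # reconstruction
    window_halfwidth_px: int = 0
    background_mode: str = "none"

    # simulator / demo experiment
    seed: int = 0
    sample_kind: str = "spots"
    noise: str = "none"  # none | poisson
    fov_px: int = 64
    pixel_size_um: float = 1.0
    steps_per_axis: int = 18
    foci_pitch_px: int = 18
    frame_period_ms: float = 0.5
    amplitude: float = 1.0
    background: float = 0.0
    overlap_frac: float = 0.14
    settle_s: float = 1.0
    tiles_nx: int = 5
    tiles_ny: int = 5
    n_lapses: int = 10

    def resolved(self) -> "FrameworkConfig":
        """Fill derived folder defaults and create the tree."""
        root = Path(self.shared_root)
        scripts = Path(self.scripts_dir) if self.scripts_dir else root / "scripts"
        data = Path(self.data_dir) if self.data_dir else root / "data"
        rec = Path(self.rec_dir) if self.rec_dir else data / "rec"
        if Path(data) not in rec.parents and rec != data:
            raise ValueError("rec_dir must be nested inside data_dir")
        for d in (root, scripts, data, rec):
            d.mkdir(parents=True, exist_ok=True)
        return replace(self, shared_root=root, scripts_dir=scripts, data_dir=data, rec_dir=rec)

    @property
    def fov_um(self) -> float:
        return self.fov_px * self.pixel_size_um


def load_config(path: Path | None = None, **overrides) -> FrameworkConfig:
    """Build a config from an optional YAML file plus keyword overrides
    (override values of None are ignored)."""
    values: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} must be a YAML mapping")
        known = {f.name for f in fields(FrameworkConfig)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(doc)
    values.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("shared_root", "scripts_dir", "data_dir", "rec_dir"):
        if values.get(key) is not None:
            values[key] = Path(values[key])
    return FrameworkConfig(**values)
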
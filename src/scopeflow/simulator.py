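"""Virtual grid-scan microscope: sample, stage and camera forward model.

The simulated instrument mimics a parallelized-RESOLFT-style acquisition:
a periodic grid of excitation foci with pitch ``p`` pixels is stepped
``s`` times along each axis (one camera frame per step), so one scan
yields an ``s² × H × W`` raw stack.  Frame ``k = ky·s + kx`` illuminates
exactly the pixels with ``x ≡ kx (mod p)`` and ``y ≡ ky (mod p)``; with
``p == s`` the s² frames partition the field of view, which makes the
reconstruction exactly invertible — the property every end-to-end test
relies on.  Optional Poisson noise models shot noise; optics blur is off
by default (the framework, not image formation, is under test).

Samples are integer-valued intensity images (photon-count-like) so that
the unsigned-16-bit camera quantization is lossless in noiseless mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "VirtualSample",
    "ScanConfig",
    "RawStack",
    "make_sample",
    "acquire_stack",
    "stack_duration_s",
]

U16_MAX = np.iinfo(np.uint16).max


@dataclass(frozen=True)
class VirtualSample:
    """A 2D intensity map on a µm grid, the simulator's ground truth."""

    image: np.ndarray
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("sample image must be 2D")
        if not np.all(np.isfinite(img)) or np.any(img < 0):
            raise ValueError("sample intensities must be finite and non-negative")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class ScanConfig:
    """Grid-scan geometry and signal model.

    ``steps_per_axis`` (s) scan steps per axis → ``s²`` frames per stack;
    ``foci_pitch_px`` (p ≥ s) is the focus grid period in camera pixels;
    ``frame_period_ms`` the per-frame exposure+readout time. Defaults
    (s = p = 18, 8 ms) give the canonical 324-frame, 2.592 s stack.
    """

    steps_per_axis: int = 18
    foci_pitch_px: int = 18
    frame_period_ms: float = 8.0
    amplitude: float = 1.0
    background: float = 0.0
    noise: Literal["none", "poisson"] = "none"
    blur_sigma_px: float = 0.0  # optional optics blur of the sample, off by default

    def __post_init__(self) -> None:
        if self.steps_per_axis < 1:
            raise ValueError("steps_per_axis must be >= 1")
        if self.foci_pitch_px < self.steps_per_axis:
            raise ValueError("foci_pitch_px must be >= steps_per_axis")
        if self.frame_period_ms <= 0:
            raise ValueError("frame_period_ms must be > 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def n_frames(self) -> int:
        return self.steps_per_axis**2

    def to_dict(self) -> dict:
        return {
            "steps_per_axis": self.steps_per_axis,
            "foci_pitch_px": self.foci_pitch_px,
            "frame_period_ms": self.frame_period_ms,
            "amplitude": self.amplitude,
            "background": self.background,
            "noise": self.noise,
            "blur_sigma_px": self.blur_sigma_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        return cls(**d)


@dataclass
class RawStack:
    """One scan's camera data: ``s² × H × W`` uint16 frames."""

    frames: np.ndarray
    scan: ScanConfig = field(default_factory=ScanConfig)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be n×H×W")
        if self.frames.shape[0] != self.scan.n_frames:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != steps_per_axis² = {self.scan.n_frames}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def make_sample(
    kind: Literal["constant", "spots", "filaments"],
    size_px: int | tuple[int, int] = 128,
    seed: int = 0,
    *,
    value: float = 100.0,
    pixel_size_um: float = 1.0,
) -> VirtualSample:
    """Deterministic synthetic specimen.

    ``constant`` — uniform intensity ``value``; ``spots`` — Gaussian
    points scattered uniformly (vesicle/bead-like); ``filaments`` —
    smoothed random-walk curves (actin-like).  Intensities are rounded to
    integers so camera quantization is exact.
    """
    if isinstance(size_px, int):
        shape = (size_px, size_px)
    else:
        shape = (int(size_px[0]), int(size_px[1]))
    if min(shape) < 16:
        raise ValueError("sample must be at least 16 px per axis")
    rng = np.random.default_rng(seed)
    h, w = shape
    if kind == "constant":
        img = np.full(shape, float(value))
    elif kind == "spots":
        img = np.zeros(shape)
        n_spots = max(5, (h * w) // 400)
        ys = rng.uniform(0, h, n_spots)
        xs = rng.uniform(0, w, n_spots)
        amps = rng.uniform(0.4, 1.0, n_spots) * value
        yy, xx = np.mgrid[0:h, 0:w]
        for y0, x0, a in zip(ys, xs, amps):
            img += a * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * 2.0**2))
    elif kind == "filaments":
        img = np.zeros(shape)
        n_fil = max(3, (h + w) // 40)
        for _ in range(n_fil):
            y = rng.uniform(0, h)
            x = rng.uniform(0, w)
            theta = rng.uniform(0, 2 * np.pi)
            for _step in range(int(2.5 * max(h, w))):
                iy, ix = int(y), int(x)
                if 0 <= iy < h and 0 <= ix < w:
                    img[iy, ix] += value / 4
                theta += rng.normal(0, 0.15)
                y += 0.7 * np.sin(theta)
                x += 0.7 * np.cos(theta)
        img = gaussian_filter(img, sigma=1.0)
        img *= value / max(img.max(), 1e-9)
    else:
        raise ValueError(f"unknown sample kind {kind!r}")
    img = np.clip(np.round(img), 0, U16_MAX)
    return VirtualSample(image=img, pixel_size_um=pixel_size_um, seed=seed)


def _crop_window(
    sample: VirtualSample, stage_xy_um: tuple[float, float], shape: tuple[int, int]
) -> np.ndarray:
    """Sample crop at a stage position; the position snaps to the nearest
    pixel (stage x → column, y → row)."""
    h, w = shape
    col0 = int(round(stage_xy_um[0] / sample.pixel_size_um))
    row0 = int(round(stage_xy_um[1] / sample.pixel_size_um))
    H, W = sample.image.shape
    if row0 < 0 or col0 < 0 or row0 + h > H or col0 + w > W:
        raise ValueError(
            f"FOV {shape} at stage {stage_xy_um} µm (pixel origin {(row0, col0)}) "
            f"lies outside the {sample.image.shape} px sample"
        )
    return sample.image[row0 : row0 + h, col0 : col0 + w]


def focus_mask(scan: ScanConfig, k: int, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels illuminated in frame ``k``."""
    s, p = scan.steps_per_axis, scan.foci_pitch_px
    ky, kx = divmod(k, s)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    mask[ky::p, kx::p] = True
    return mask


def acquire_stack(
    sample: VirtualSample,
    stage_xy_um: tuple[float, float],
    scan: ScanConfig,
    fov_px: tuple[int, int] = (64, 64),
    rng: np.random.Generator | None = None,
) -> RawStack:
    """Simulate one grid scan at a stage position.

    Frame ``k = ky·s + kx`` (row-major over scan steps) reads
    ``background + amplitude·S`` at its focus pixels and ``background``
    elsewhere, where ``S`` is the sample crop for this stage position.
    Poisson noise, if enabled, is applied per pixel; values are rounded
    and clipped into the unsigned-16-bit camera range.
    """
    s, p = scan.steps_per_axis, scan.foci_pitch_px
    crop = _crop_window(sample, stage_xy_um, fov_px)
    if scan.blur_sigma_px > 0:
        crop = gaussian_filter(crop, sigma=scan.blur_sigma_px)
    signal = scan.background + scan.amplitude * crop
    frames = np.full((scan.n_frames, *fov_px), scan.background, dtype=np.float64)
    for k in range(scan.n_frames):
        ky, kx = divmod(k, s)
        frames[k, ky::p, kx::p] = signal[ky::p, kx::p]
    if scan.noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(sample.seed)
        frames = rng.poisson(frames).astype(np.float64)
    frames = np.clip(np.round(frames), 0, U16_MAX).astype(np.uint16)
    return RawStack(frames=frames, scan=scan)


def stack_duration_s(scan: ScanConfig) -> float:
    """Acquisition time of one stack: s² frames × frame period."""
    return scan.n_frames * scan.frame_period_ms / 1000.0
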
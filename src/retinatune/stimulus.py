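"""Artificial visual stimuli: moving white bars and full-field flashes.

Stimuli are time-ordered stacks of grayscale frames with a physical pixel
scale, generated deterministically (no randomness, no anti-aliasing) so that
identical arguments always yield bit-identical frame stacks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FrameSequence",
    "make_bar_stimulus",
    "make_flash_stimulus",
    "load_frames",
    "save_frames",
    "DEFAULT_PIXEL_SCALE_UM",
]

#: 4 mm field mapped onto 154 px -> ~26 um per pixel.
DEFAULT_PIXEL_SCALE_UM = 26.0

_VALID_DIRECTIONS = tuple(range(0, 360, 45))


@dataclass(frozen=True)
class FrameSequence:
    """A stimulus: frames (time, height, width) or (time, height, width, 3).

    Intensities are dimensionless in [0, 1].
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_scale_um: float
    duration_ms: float = field(default=0.0)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim not in (3, 4):
            raise ValueError("frames must be 3-D (t,h,w) or 4-D (t,h,w,3)")
        if frames.ndim == 4 and frames.shape[-1] != 3:
            raise ValueError("colour frames must have exactly 3 channels")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be positive")
        if not (self.pixel_scale_um > 0):
            raise ValueError("pixel_scale_um must be positive")
        if frames.size and (frames.min() < 0 or frames.max() > 1):
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "frames", frames)
        if self.duration_ms == 0.0:
            object.__setattr__(
                self, "duration_ms", 1000.0 * frames.shape[0] / self.frame_rate_hz
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def is_color(self) -> bool:
        return self.frames.ndim == 4

    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (R, G, B) stacks; grayscale input replicates intensity."""
        if self.is_color():
            return self.frames[..., 0], self.frames[..., 1], self.frames[..., 2]
        return self.frames, self.frames, self.frames

    def intensity(self) -> np.ndarray:
        """Mean of R, G, B (equals frames for grayscale input)."""
        if self.is_color():
            return self.frames.mean(axis=-1)
        return self.frames


def _bar_frames(
    height_px: int,
    width_px: int,
    bar_px: int,
    direction_deg: int,
    n_frames_per_sweep: int,
    n_sweeps: int,
) -> np.ndarray:
    """Rasterise one bar sweep and tile it.

    Directions >= 180 deg are produced by rotating the opposite direction's
    frames by 180 deg, which guarantees the exact mirror symmetry between a
    sweep and its reverse.
    """
    if direction_deg >= 180:
        base = _bar_frames(
            height_px, width_px, bar_px, direction_deg - 180, n_frames_per_sweep, n_sweeps
        )
        return base[:, ::-1, ::-1].copy()

    theta = math.radians(direction_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    # projection of each pixel centre onto the motion axis
    proj = xx * ux + yy * uy
    pmin, pmax = proj.min(), proj.max()
    travel = (pmax - pmin) + bar_px  # bar enters fully and exits fully
    frames = np.zeros((n_frames_per_sweep, height_px, width_px), dtype=np.float64)
    half = bar_px / 2.0
    for f in range(n_frames_per_sweep):
        centre = (pmin - half) + travel * f / n_frames_per_sweep
        d = proj - centre
        # half-open interval -> an integer-width bar covers exactly bar_px
        # columns at every fully-on-screen position (cardinal directions)
        frames[f][(d >= -half) & (d < half)] = 1.0
    return np.tile(frames, (n_sweeps, 1, 1))


def make_bar_stimulus(
    height_px: int,
    width_px: int,
    bar_width_um: float = 250.0,
    direction_deg: int = 0,
    sweep_freq_hz: float = 1.0,
    frame_rate_hz: float = 60.0,
    n_sweeps: int = 1,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
) -> FrameSequence:
    """White bar on black background sweeping across the field.

    The bar is perpendicular to its motion axis, starts just off-screen and
    fully exits before the next sweep begins; one traversal takes
    ``1 / sweep_freq_hz`` seconds.
    """
    if height_px <= 0 or width_px <= 0:
        raise ValueError("frame dimensions must be positive")
    if direction_deg % 45 != 0 or not (0 <= direction_deg < 360):
        raise ValueError("direction must be a multiple of 45 deg in [0, 360)")
    if bar_width_um < pixel_scale_um:
        raise ValueError("bar must be at least one pixel wide")
    if n_sweeps <= 0:
        raise ValueError("n_sweeps must be positive")
    if sweep_freq_hz <= 0 or frame_rate_hz <= 0:
        raise ValueError("rates must be positive")

    bar_px = int(round(bar_width_um / pixel_scale_um))
    n_frames_per_sweep = int(round(frame_rate_hz / sweep_freq_hz))
    frames = _bar_frames(
        height_px, width_px, bar_px, direction_deg, n_frames_per_sweep, n_sweeps
    )
    return FrameSequence(frames, frame_rate_hz, pixel_scale_um)


def make_flash_stimulus(
    on_ms: float = 700.0,
    off_ms: float = 2300.0,
    repeats: int = 1,
    height_px: int = 120,
    width_px: int = 154,
    frame_rate_hz: float = 60.0,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
) -> FrameSequence:
    """Repeated full-field flashes: intensity 1 for on_ms, then 0 for off_ms."""
    if repeats <= 0:
        raise ValueError("repeats must be positive")
    if height_px <= 0 or width_px <= 0:
        raise ValueError("frame dimensions must be positive")
    period_ms = 1000.0 / frame_rate_hz
    if on_ms < period_ms or off_ms < period_ms:
        raise ValueError("on/off intervals must last at least one frame period")

    n_on = int(round(on_ms / 1000.0 * frame_rate_hz))
    n_off = int(round(off_ms / 1000.0 * frame_rate_hz))
    cycle = np.concatenate([np.ones(n_on), np.zeros(n_off)])
    values = np.tile(cycle, repeats)
    frames = np.broadcast_to(
        values[:, None, None], (values.size, height_px, width_px)
    ).copy()
    return FrameSequence(
        frames, frame_rate_hz, pixel_scale_um, duration_ms=repeats * (on_ms + off_ms)
    )


def save_frames(seq: FrameSequence, path: str | Path) -> None:
    """Write a 16-bit multipage TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.round(seq.frames * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "frame_rate_hz": seq.frame_rate_hz,
                "pixel_scale_um": seq.pixel_scale_um,
                "duration_ms": seq.duration_ms,
                "n_frames": seq.n_frames,
            }
        )
    )


def load_frames(path: str | Path) -> FrameSequence:
    """Load a stimulus written by :func:`save_frames`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        data = tifffile.imread(path)
    except (json.JSONDecodeError, tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"unreadable stimulus file {path}: {exc}") from exc
    for key in ("frame_rate_hz", "pixel_scale_um", "n_frames"):
        if key not in meta:
            raise ValueError(f"metadata sidecar missing key {key!r}")
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"declared {meta['n_frames']} frames but file holds {data.shape[0]}"
        )
    frames = data.astype(np.float64) / 65535.0
    return FrameSequence(
        frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_scale_um=float(meta["pixel_scale_um"]),
        duration_ms=float(meta.get("duration_ms", 0.0)),
    )
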
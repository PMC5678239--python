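"""Synthetic visual scenes: a solid-hue target over a mixed background.

This module stands in for the RGB camera and the physical scene. It renders
frames as ``(height, width, 3)`` uint8 arrays containing an axis-aligned
solid-color target rectangle at a controlled horizontal offset, over a static
"mixed coloration" background that may include target-colored distractor
pixels (emulating incidental red objects in the field of view). It also
defines 1-D target trajectories (position in inches over time), including
intervals where the target is out of the camera's field of view.

Rendering is deterministic: a given :class:`SceneConfig` and target offset
always produce a bit-identical frame.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Sentinel for "target not visible" (out of view or removed from the scene).
ABSENT = None

#: Default non-target background colors (muted grays/greens/blues/tans).
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (96, 96, 104),
    (70, 110, 70),
    (60, 70, 120),
    (120, 115, 90),
)

_BG_BLOCK = 16  # side of the background color tiles, px


def hue_to_rgb(hue_degrees: float) -> tuple[int, int, int]:
    """Fully saturated, full-value RGB triple for a hue in degrees."""
    r, g, b = colorsys.hsv_to_rgb((hue_degrees % 360.0) / 360.0, 1.0, 1.0)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


@dataclass(frozen=True)
class SceneConfig:
    """Static description of the rendered scene.

    ``distractor_red_fraction`` is the i.i.d. per-pixel probability that a
    background pixel is recolored to the target hue. It should stay well
    below the level at which distractors alone could flip the sign of the
    left/right strip difference downstream (for the defaults, the distractor
    contribution to the difference has a standard deviation of ~25 px,
    versus the 500 px stimulation quantum); this is documented, not enforced.
    """

    frame_width: int = 640
    frame_height: int = 480
    target_hue: float = 0.0  # degrees; 0 = red
    target_width: int = 200
    target_height: int = 150
    background_palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE
    distractor_red_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.target_width <= 0 or self.target_height <= 0:
            raise ValueError("target dimensions must be positive")
        if self.target_width > self.frame_width or self.target_height > self.frame_height:
            raise ValueError("target must fit inside the frame")
        if not 0.0 <= self.distractor_red_fraction < 1.0:
            raise ValueError("distractor_red_fraction must be in [0, 1)")
        if not self.background_palette:
            raise ValueError("background palette must not be empty")


@lru_cache(maxsize=8)
def _background(scene: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Static background image and the boolean distractor mask (cached)."""
    h, w = scene.frame_height, scene.frame_width
    yy, xx = np.mgrid[0:h, 0:w]
    palette = np.asarray(scene.background_palette, dtype=np.uint8)
    idx = (xx // _BG_BLOCK + yy // _BG_BLOCK) % len(palette)
    bg = palette[idx]
    rng = np.random.default_rng(scene.seed)
    distractors = rng.random((h, w)) < scene.distractor_red_fraction
    bg[distractors] = hue_to_rgb(scene.target_hue)
    bg.setflags(write=False)
    distractors.setflags(write=False)
    return bg, distractors


def distractor_mask(scene: SceneConfig) -> np.ndarray:
    """Boolean mask of background pixels recolored to the target hue."""
    return _background(scene)[1]


def render_frame(scene: SceneConfig, target_px_offset: float | None = ABSENT) -> np.ndarray:
    """Render one frame; the target center sits ``target_px_offset`` px right
    of the frame center (``ABSENT``/None renders background only).

    The target is drawn as a solid axis-aligned rectangle of the target hue,
    vertically centered, horizontally clipped to the frame. If an offset is
    given, at least one target column must fall inside the frame.
    """
    bg, _ = _background(scene)
    frame = bg.copy()
    if target_px_offset is not ABSENT:
        w, h = scene.frame_width, scene.frame_height
        center = w / 2.0 + float(target_px_offset)
        c0 = int(round(center - scene.target_width / 2.0))
        c1 = c0 + scene.target_width
        c0v, c1v = max(c0, 0), min(c1, w)
        if c1v <= c0v:
            raise ValueError("target offset places the target entirely outside the frame")
        r0 = (h - scene.target_height) // 2
        frame[r0 : r0 + scene.target_height, c0v:c1v] = hue_to_rgb(scene.target_hue)
    return frame


def visible_target_area(scene: SceneConfig, target_px_offset: float | None) -> int:
    """Number of target pixels inside the frame for a given offset (0 if absent)."""
    if target_px_offset is ABSENT:
        return 0
    w = scene.frame_width
    center = w / 2.0 + float(target_px_offset)
    c0 = int(round(center - scene.target_width / 2.0))
    c1 = c0 + scene.target_width
    cols = max(0, min(c1, w) - max(c0, 0))
    return cols * scene.target_height


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySpec:
    """Target x-position (inches) over time, with optional absence intervals.

    ``kind`` selects the interpretation of ``positions``:

    - ``"static"``: ``positions = (x,)``, constant position.
    - ``"sweep"``: ``positions = (start, end)``, linear sweep over ``duration``.
    - ``"piecewise"``: ``positions = ((t0, x0), (t1, x1), ...)`` knots,
      linearly interpolated; ``t0 = 0`` and ``t_last = duration``.

    ``absent_windows`` are half-open ``[a, b)`` intervals during which the
    target is out of the camera's field of view regardless of position.
    """

    kind: str
    duration: float
    positions: tuple
    absent_windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind not in ("static", "sweep", "piecewise"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.kind == "static" and len(self.positions) != 1:
            raise ValueError("static trajectory takes a single position")
        if self.kind == "sweep" and len(self.positions) != 2:
            raise ValueError("sweep trajectory takes (start, end)")
        if self.kind == "piecewise":
            ts = [t for t, _ in self.positions]
            if ts != sorted(ts) or ts[0] != 0 or abs(ts[-1] - self.duration) > 1e-9:
                raise ValueError("piecewise knots must span [0, duration] in order")
        for a, b in self.absent_windows:
            if not 0 <= a < b <= self.duration:
                raise ValueError("absent windows must be ordered sub-intervals of [0, duration]")


def static_target(x: float, duration: float) -> TrajectorySpec:
    return TrajectorySpec("static", duration, (float(x),))


def linear_sweep(start: float, end: float, duration: float) -> TrajectorySpec:
    return TrajectorySpec("sweep", duration, (float(start), float(end)))


def triangle_sweep(amplitude: float, duration: float) -> TrajectorySpec:
    """Full-range sweep starting at midline: 0 -> +A -> -A -> 0."""
    a = float(amplitude)
    d = float(duration)
    knots = ((0.0, 0.0), (d / 4, a), (3 * d / 4, -a), (d, 0.0))
    return TrajectorySpec("piecewise", d, knots)


def with_absence(spec: TrajectorySpec, windows: tuple[tuple[float, float], ...]) -> TrajectorySpec:
    return replace(spec, absent_windows=spec.absent_windows + tuple(windows))


def sample_trajectory(spec: TrajectorySpec, t: float) -> float | None:
    """Target position in inches at time ``t``, or ``ABSENT``.

    Raises a domain error for ``t`` outside ``[0, duration]``.
    """
    if not 0.0 <= t <= spec.duration:
        raise ValueError(f"t={t} outside trajectory domain [0, {spec.duration}]")
    for a, b in spec.absent_windows:
        if a <= t < b:
            return ABSENT
    if spec.kind == "static":
        return spec.positions[0]
    if spec.kind == "sweep":
        start, end = spec.positions
        return start + (end - start) * t / spec.duration
    knots = np.asarray(spec.positions, dtype=float)
    return float(np.interp(t, knots[:, 0], knots[:, 1]))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_frame(path: str | Path, frame: np.ndarray) -> None:
    iio.imwrite(Path(path), frame)


def read_frame(path: str | Path) -> np.ndarray:
    frame = iio.imread(Path(path))
    if frame.ndim == 3 and frame.shape[2] == 4:  # drop alpha
        frame = frame[:, :, :3]
    return np.asarray(frame, dtype=np.uint8)


def trajectory_to_csv(spec: TrajectorySpec, path: str | Path, dt: float = 0.1) -> pd.DataFrame:
    """Tabulate the trajectory at step ``dt`` and write (t, x_inches, visible)."""
    ts = np.arange(0.0, spec.duration + dt / 2, dt)
    ts = ts[ts <= spec.duration]
    rows = []
    for t in ts:
        x = sample_trajectory(spec, float(t))
        rows.append({"t": float(t), "x_inches": np.nan if x is ABSENT else x, "visible": x is not ABSENT})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
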
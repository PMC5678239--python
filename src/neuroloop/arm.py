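"""One-dimensional robot arm with an arm-mounted camera.

The arm moves left/right at constant speed under MOVE/STOP commands, clamped
to a symmetric range around the midpoint (0 inches). The camera is rigidly
mounted on the hand, so the view center always equals the arm position; a
target appears in the frame at a pixel offset proportional to its distance
from the arm, or not at all when outside the field of view. When the target
has been absent for a sustained run of frames the arm homes back to the
midpoint, reproducing the return-to-center behavior seen when the target is
removed from the camera's view.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .decoder import MotionCommand
from .scene import ABSENT

DEFAULT_RANGE = 10.0  # inches, symmetric about the midpoint
DEFAULT_SPEED = 1.0  # inches/s
DEFAULT_FOV = 10.0  # inches visible across the frame
DEFAULT_HOMING_PATIENCE = 10  # consecutive target-absent frames before homing


@dataclass(frozen=True)
class ArmState:
    """Arm position (inches from the midpoint) and its motion constants."""

    position: float = 0.0
    speed: float = DEFAULT_SPEED
    range: float = DEFAULT_RANGE

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.range <= 0:
            raise ValueError("speed and range must be positive")
        if abs(self.position) > self.range + 1e-12:
            raise ValueError("position outside the arm's range")


@dataclass(frozen=True)
class CameraModel:
    """Linear projection of the arm-mounted camera."""

    field_of_view: float = DEFAULT_FOV  # inches spanned by the frame width
    frame_width: int = 640  # px

    @property
    def pixels_per_inch(self) -> float:
        return self.frame_width / self.field_of_view


def apply_command(state: ArmState, cmd: MotionCommand, dt: float) -> ArmState:
    """Advance the arm by one command interval; position clamps at the range."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cmd is MotionCommand.STOP:
        return state
    step = state.speed * dt
    if cmd is MotionCommand.MOVE_LEFT:
        step = -step
    pos = min(max(state.position + step, -state.range), state.range)
    return replace(state, position=pos)


def view_offset(
    cam: CameraModel, arm: ArmState, target_pos: float | None
) -> float | None:
    """Pixel offset of the target from the frame center, or ``ABSENT``.

    The view is centered on the arm; a target more than half the field of
    view away falls outside the frame.
    """
    if target_pos is ABSENT:
        return ABSENT
    delta = target_pos - arm.position
    if abs(delta) > cam.field_of_view / 2.0:
        return ABSENT
    return delta * cam.pixels_per_inch


def homing_step(
    state: ArmState,
    frames_without_target: int,
    patience: int = DEFAULT_HOMING_PATIENCE,
    dt: float = 0.2,
) -> ArmState:
    """Move toward the midpoint once the target has been absent long enough.

    No-op until ``frames_without_target`` reaches ``patience``; then the arm
    steps toward 0 at its speed, stopping exactly at 0 (no overshoot).
    """
    if patience < 1:
        raise ValueError("patience must be at least 1")
    if frames_without_target < patience or state.position == 0.0:
        return state
    step = min(state.speed * dt, abs(state.position))
    pos = state.position - step if state.position > 0 else state.position + step
    return replace(state, position=pos)


def quantize_position(position: float, increment: float = 0.25) -> float:
    """Snap a position to the reporting increment (default 0.25 inches)."""
    return round(position / increment) * increment
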
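"""Activation-vector decoder: spikes -> leaky activations -> motor commands.

Implements the recording-side half of the closed loop. Spikes are threshold
crossings exceeding three standard deviations of the channel within its 3-s
recording window. Each channel feeds a leaky integrator

    A_n(t_i) = A_n(t_{i-1}) * exp(-beta * (t_i - t_{i-1}))

incremented by 1 per detected spike, so at any time
``A_n(t) = sum_k exp(-beta * (t - t_k))`` over that channel's spike times.
Every 0.2 s the 60-element activation vector is compared by Euclidean
distance with fixed "left" and "right" template vectors (elevated activity
on the corresponding hemisphere); if the nearer template is within the
acceptance distance and the two distances are not tied, the corresponding
motion command is emitted, otherwise STOP.

The default command mapping is contralateral, closing the loop of the full
system: right-hemisphere-dominant activity (evoked by a target seen on the
left) drives the arm left.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .mea import MEALayout, N_CHANNELS, VoltageWindow

DECISION_PERIOD = 0.2  # s
DEFAULT_BETA = 5.0  # 1/s; decay time constant equal to the decision period
DEFAULT_THRESHOLD_MULT = 3.0
DEFAULT_REFRACTORY = 0.002  # s


class MotionCommand(Enum):
    MOVE_LEFT = "move_left"
    MOVE_RIGHT = "move_right"
    STOP = "stop"


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and standard deviation of one recording window."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass(frozen=True)
class SpikeEvents:
    """Detected threshold crossings: parallel channel/time arrays."""

    channels: np.ndarray
    times: np.ndarray

    def __len__(self) -> int:
        return len(self.channels)


def channel_stats(samples: np.ndarray) -> ChannelStats:
    """Mean and (population) SD per channel of a (n_channels, n) trace."""
    return ChannelStats(mean=samples.mean(axis=1), sd=samples.std(axis=1))


def detect_crossings(
    block: np.ndarray,
    stats: ChannelStats,
    t_start: float,
    sample_rate: int,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
    refractory: float = DEFAULT_REFRACTORY,
    two_sided: bool = True,
    last_event_time: np.ndarray | None = None,
) -> SpikeEvents:
    """Threshold a trace block against precomputed channel statistics.

    A sample is a crossing when its deviation from the channel mean exceeds
    ``threshold_mult`` channel SDs (absolute deviation by default; set
    ``two_sided=False`` for positive-only). Crossings closer than
    ``refractory`` to the previous kept event on the same channel are merged
    into it, so a single deflection yields a single event.
    ``last_event_time`` (updated in place) carries the refractory state
    across consecutive blocks.
    """
    dev = block - stats.mean[:, None]
    if two_sided:
        dev = np.abs(dev)
    hits = dev > threshold_mult * stats.sd[:, None]
    if last_event_time is None:
        last_event_time = np.full(block.shape[0], -np.inf)
    channels: list[int] = []
    times: list[float] = []
    eps = 1e-12
    for ch in np.nonzero(hits.any(axis=1))[0]:
        for k in np.nonzero(hits[ch])[0]:
            t = t_start + k / sample_rate
            if t - last_event_time[ch] >= refractory - eps:
                channels.append(int(ch))
                times.append(t)
                last_event_time[ch] = t
    order = np.argsort(times, kind="stable")
    return SpikeEvents(
        channels=np.asarray(channels, dtype=int)[order],
        times=np.asarray(times)[order],
    )


def detect_spikes(
    window: VoltageWindow,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
    refractory: float = DEFAULT_REFRACTORY,
    two_sided: bool = True,
) -> SpikeEvents:
    """Detect spikes in a full window using that window's own statistics.

    Zero-variance channels yield no events by definition (no sample can
    exceed 3 x 0 deviation strictly when all deviations are 0).
    """
    stats = channel_stats(window.samples)
    return detect_crossings(
        window.samples,
        stats,
        t_start=window.t0,
        sample_rate=window.sample_rate,
        threshold_mult=threshold_mult,
        refractory=refractory,
        two_sided=two_sided,
    )


# ---------------------------------------------------------------------------
# Activation vector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationState:
    """60-element leaky spike-count vector with its last update time."""

    values: np.ndarray
    last_update_time: float
    beta: float = DEFAULT_BETA

    @classmethod
    def zeros(cls, beta: float = DEFAULT_BETA, t: float = 0.0, n: int = N_CHANNELS) -> "ActivationState":
        return cls(values=np.zeros(n), last_update_time=t, beta=beta)


def update_activation(
    state: ActivationState, events: SpikeEvents | np.ndarray | None, t: float
) -> ActivationState:
    """Decay the activation vector to time ``t``, then add the event batch.

    ``events`` may be a :class:`SpikeEvents` batch (all counted at ``t``;
    callers wanting exact per-event decay pass batches grouped by event
    time), a per-channel count array, or None. ``t`` must not precede the
    last update.
    """
    if t < state.last_update_time:
        if state.last_update_time - t < 1e-9:  # float jitter on shared boundaries
            t = state.last_update_time
        else:
            raise ValueError(
                f"update time {t} precedes last update {state.last_update_time}"
            )
    values = state.values * np.exp(-state.beta * (t - state.last_update_time))
    if events is not None:
        if isinstance(events, SpikeEvents):
            counts = np.bincount(events.channels, minlength=len(state.values))
        else:
            counts = np.asarray(events)
        values = values + counts
    return ActivationState(values=values, last_update_time=t, beta=state.beta)


def apply_events_chronologically(
    state: ActivationState, events: SpikeEvents, t_end: float
) -> ActivationState:
    """Feed events through the recursion in time order, then decay to ``t_end``.

    Events sharing a timestamp are applied as one batch; the result equals
    the closed form ``A_n(t_end) = sum_k exp(-beta (t_end - t_k))`` plus the
    decayed prior state.
    """
    if len(events):
        order = np.argsort(events.times, kind="stable")
        times = events.times[order]
        chans = events.channels[order]
        for t in np.unique(times):
            batch = SpikeEvents(channels=chans[times == t], times=times[times == t])
            state = update_activation(state, batch, float(t))
    return update_activation(state, None, t_end)


# ---------------------------------------------------------------------------
# Template classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceVectors:
    """Fixed left/right activation templates and the acceptance radius."""

    left: np.ndarray
    right: np.ndarray
    accept_distance: float

    def __post_init__(self) -> None:
        if np.array_equal(self.left, self.right):
            raise ValueError("left and right reference vectors must differ")
        if self.accept_distance <= 0:
            raise ValueError("accept_distance must be positive")


def default_references(
    layout: MEALayout, level: float = 2.0, accept_distance: float | None = None
) -> ReferenceVectors:
    """Templates with ``level`` on one hemisphere's channels and 0 elsewhere.

    The acceptance radius defaults to the template norm ``level * sqrt(30)``,
    so the rest state (all-zero activation) sits exactly on the acceptance
    boundary of both templates.
    """
    left = np.where(layout.is_left, float(level), 0.0)
    right = np.where(layout.is_right, float(level), 0.0)
    if accept_distance is None:
        accept_distance = float(np.linalg.norm(left))
    return ReferenceVectors(left=left, right=right, accept_distance=accept_distance)


def calibrate_reference_level(activations: np.ndarray, hemisphere_mask: np.ndarray) -> float:
    """Template level from observed activity: mean per-channel activation on
    the stimulated hemisphere under sustained stimulation.

    ``activations`` is (n_snapshots, n_channels) of activation vectors
    sampled at decision ticks while one hemisphere is driven.
    """
    activations = np.atleast_2d(np.asarray(activations))
    return float(activations[:, np.asarray(hemisphere_mask, dtype=bool)].mean())


def template_distances(state: ActivationState, refs: ReferenceVectors) -> tuple[float, float]:
    """Euclidean distances (d_left, d_right) from the activation vector."""
    d_left = float(np.linalg.norm(state.values - refs.left))
    d_right = float(np.linalg.norm(state.values - refs.right))
    return d_left, d_right


def classify(
    state: ActivationState,
    refs: ReferenceVectors,
    tie_margin: float = 1e-6,
    contralateral: bool = True,
) -> MotionCommand:
    """Match the activation vector to a template and emit a command.

    STOP when neither template is within the acceptance distance, or when the
    two distances are within ``tie_margin`` of each other (no clear side).
    With the default contralateral mapping the right template winning emits
    MOVE_LEFT (and mirror-image); ``contralateral=False`` inverts.
    """
    d_left, d_right = template_distances(state, refs)
    if min(d_left, d_right) > refs.accept_distance:
        return MotionCommand.STOP
    if abs(d_left - d_right) <= tie_margin:
        return MotionCommand.STOP
    left_wins = d_left < d_right
    if contralateral:
        return MotionCommand.MOVE_RIGHT if left_wins else MotionCommand.MOVE_LEFT
    return MotionCommand.MOVE_LEFT if left_wins else MotionCommand.MOVE_RIGHT


# ---------------------------------------------------------------------------
# Windowed decoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecisionRecord:
    t: float
    d_left: float
    d_right: float
    command: MotionCommand


def decode_window(
    window: VoltageWindow,
    refs: ReferenceVectors,
    state: ActivationState | None = None,
    decision_period: float = DECISION_PERIOD,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
    refractory: float = DEFAULT_REFRACTORY,
    two_sided: bool = True,
    tie_margin: float = 1e-6,
    contralateral: bool = True,
) -> tuple[list[DecisionRecord], ActivationState]:
    """Decode one recording window into its sequence of motion commands.

    Spikes are detected against the window's own statistics; activation
    updates run chronologically through the event stream; a decision is
    taken every ``decision_period`` seconds (15 per 3-s window), each using
    only events up to its decision time.
    """
    if state is None:
        state = ActivationState.zeros(t=window.t0)
    events = detect_spikes(window, threshold_mult, refractory, two_sided)
    n_dec = int(round(window.duration / decision_period))
    records: list[DecisionRecord] = []
    prev_tick = window.t0 - 1.0 / window.sample_rate  # include the t0 sample
    for j in range(n_dec):
        tick = window.t0 + (j + 1) * decision_period
        in_tick = (events.times > prev_tick + 1e-12) & (events.times <= tick + 1e-12)
        prev_tick = tick
        batch = SpikeEvents(channels=events.channels[in_tick], times=events.times[in_tick])
        state = apply_events_chronologically(state, batch, tick)
        d_left, d_right = template_distances(state, refs)
        cmd = classify(state, refs, tie_margin, contralateral)
        records.append(DecisionRecord(t=tick, d_left=d_left, d_right=d_right, command=cmd))
    return records, state


def decisions_to_csv(records: list[DecisionRecord], path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"t": r.t, "d_left": r.d_left, "d_right": r.d_right, "command": r.command.value}
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return df
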
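"""Simulated two-hemisphere cultured network on a 60-electrode array.

A stand-in for the scalpel-segmented ex vivo cortical culture: each of the 60
channels of a corner-less 8x8 MEA carries Gaussian recording noise plus
single-sample spike deflections drawn from an inhomogeneous Poisson process.
The rate on a channel is its hemisphere's spontaneous baseline plus an evoked
increment proportional to the number of stimulation signals currently active
on that hemisphere (each signal raises the rate for ``evoked_duration``
seconds after delivery). Stimulation of one half never adds spikes to the
other half, mirroring the confinement of responses within the stimulated
segment of the severed culture.

Traces are produced in 3-second windows of 3000 samples (1000 samples/s),
the recording granularity consumed by the decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vision import Side, StimulusBatch

SAMPLE_RATE = 1000  # samples/s
WINDOW_S = 3.0  # recording window length, s
N_CHANNELS = 60
GRID = 8


@dataclass(frozen=True)
class MEALayout:
    """Corner-less 8x8 electrode grid split into left/right hemispheres.

    Channels are indexed row-major over the grid with the four corner
    positions absent (64 - 4 = 60). Columns 0-3 form the LEFT hemisphere,
    columns 4-7 the RIGHT; 30 channels each.
    """

    rows: np.ndarray
    cols: np.ndarray
    is_left: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.rows)

    @property
    def is_right(self) -> np.ndarray:
        return ~self.is_left

    def hemisphere_mask(self, side: Side) -> np.ndarray:
        if side is Side.LEFT:
            return self.is_left
        if side is Side.RIGHT:
            return self.is_right
        raise ValueError(f"not a hemisphere: {side}")


def make_layout() -> MEALayout:
    """The standard 60-electrode layout: 8x8 grid minus the four corners."""
    corners = {(0, 0), (0, GRID - 1), (GRID - 1, 0), (GRID - 1, GRID - 1)}
    rows, cols = [], []
    for r in range(GRID):
        for c in range(GRID):
            if (r, c) not in corners:
                rows.append(r)
                cols.append(c)
    rows = np.array(rows)
    cols = np.array(cols)
    layout = MEALayout(rows=rows, cols=cols, is_left=cols < GRID // 2)
    assert layout.n_channels == N_CHANNELS
    return layout


@dataclass(frozen=True)
class NetworkConfig:
    """Rate-model parameters of the simulated culture.

    ``evoked_rate_gain`` is the firing-rate increment (spikes/s/channel) per
    concurrently active stimulation signal; each signal stays active for
    ``evoked_duration`` seconds (the length of the digitized synaptic
    stimulus). Spikes ride on Gaussian noise as single-sample deflections of
    ``spike_amplitude``; a biphasic (+/-) two-sample shape is available but
    off by default so that ground-truth spike counts stay exactly countable.
    """

    baseline_rate_left: float = 2.0  # spikes/s/channel
    baseline_rate_right: float = 2.0
    evoked_rate_gain: float = 0.3  # spikes/s/channel per active signal
    evoked_duration: float = 1.0  # s
    spike_amplitude: float = 6.0  # trace units
    noise_sd: float = 1.0
    sample_rate: int = SAMPLE_RATE
    seed: int = 0
    biphasic: bool = False

    def __post_init__(self) -> None:
        if min(self.baseline_rate_left, self.baseline_rate_right) < 0:
            raise ValueError("baseline rates must be non-negative")
        if self.evoked_rate_gain < 0 or self.evoked_duration < 0:
            raise ValueError("evoked gain and duration must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.spike_amplitude <= 3 * self.noise_sd:
            warnings.warn(
                "spike_amplitude <= 3x noise_sd: injected spikes will often "
                "fall under the detection threshold",
                stacklevel=2,
            )


@dataclass
class VoltageWindow:
    """One 60-channel recording window plus the injected ground truth."""

    t0: float
    samples: np.ndarray  # (60, n) float
    sample_rate: int = SAMPLE_RATE
    truth_channels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    truth_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def rate_matrix(
    cfg: NetworkConfig,
    layout: MEALayout,
    stims: list[tuple[float, StimulusBatch]],
    t0: float,
    n_samples: int,
) -> np.ndarray:
    """Per-channel, per-sample firing rate (spikes/s) over a sample block.

    Sample ``k`` of the block is taken at time ``t0 + k / sample_rate``. A
    stimulus delivered at time ``ts`` with count ``c`` adds
    ``evoked_rate_gain * c`` to every channel of its hemisphere for samples
    with ``ts <= t < ts + evoked_duration``. Only LEFT/RIGHT sides are valid.
    """
    fs = cfg.sample_rate
    rates = np.empty((layout.n_channels, n_samples))
    rates[layout.is_left] = cfg.baseline_rate_left
    rates[layout.is_right] = cfg.baseline_rate_right
    for ts, batch in stims:
        if batch.side is Side.NONE or batch.count == 0:
            continue
        mask = layout.hemisphere_mask(batch.side)
        k0 = int(np.ceil((ts - t0) * fs - 1e-9))
        k1 = int(np.ceil((ts + cfg.evoked_duration - t0) * fs - 1e-9))
        k0, k1 = max(k0, 0), min(k1, n_samples)
        if k1 > k0:
            rates[mask, k0:k1] += cfg.evoked_rate_gain * batch.count
    return rates


def sample_block(
    rng: np.random.Generator, cfg: NetworkConfig, rates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one trace block: noise plus Poisson spikes at the given rates.

    Spike occupancy per 1-ms sample is Bernoulli with
    ``p = 1 - exp(-rate/fs)`` (Poisson thinning; at most one spike per
    sample). Returns ``(trace, spike_channels, spike_sample_indices)`` where
    the latter two are the injected ground truth, ordered by sample index.
    """
    p = -np.expm1(-rates / cfg.sample_rate)
    spikes = rng.random(rates.shape) < p
    trace = rng.normal(0.0, cfg.noise_sd, size=rates.shape)
    trace[spikes] += cfg.spike_amplitude
    if cfg.biphasic:
        ch, k = np.nonzero(spikes)
        nxt = k + 1
        ok = nxt < rates.shape[1]
        trace[ch[ok], nxt[ok]] -= cfg.spike_amplitude
    ch, k = np.nonzero(spikes)
    order = np.argsort(k, kind="stable")
    return trace, ch[order], k[order]


def simulate_window(
    cfg: NetworkConfig,
    layout: MEALayout,
    stims: list[tuple[float, StimulusBatch]] = (),
    t0: float = 0.0,
    duration: float = WINDOW_S,
    rng: np.random.Generator | None = None,
) -> VoltageWindow:
    """Simulate one recording window under a stimulation schedule.

    Deterministic for a fixed ``cfg.seed`` and ``t0`` (the per-window RNG is
    derived from both, so consecutive windows differ while re-simulation of
    the same window is bit-identical). Stimulation times must fall within
    ``[t0, t0 + duration)``.
    """
    n = int(round(duration * cfg.sample_rate))
    for ts, batch in stims:
        if batch.side not in (Side.LEFT, Side.RIGHT, Side.NONE):
            raise ValueError(f"malformed stimulation side: {batch.side!r}")
        if not t0 <= ts < t0 + duration:
            raise ValueError(f"stimulation time {ts} outside window [{t0}, {t0 + duration})")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), int(round(t0 * cfg.sample_rate))])
        )
    rates = rate_matrix(cfg, layout, list(stims), t0, n)
    trace, ch, k = sample_block(rng, cfg, rates)
    return VoltageWindow(
        t0=t0,
        samples=trace,
        sample_rate=cfg.sample_rate,
        truth_channels=ch,
        truth_times=t0 + k / cfg.sample_rate,
    )


def ideal_network_config(seed: int = 0) -> NetworkConfig:
    """Evoked-only network: zero spontaneous baseline on both hemispheres.

    All spiking is stimulation-driven, so closed-loop behavior is governed
    purely by the visual drive (up to detection noise on the recording).
    """
    return NetworkConfig(baseline_rate_left=0.0, baseline_rate_right=0.0, seed=seed)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def window_to_csv(window: VoltageWindow, path) -> None:
    """Long-format CSV (channel, sample_index, value)."""
    n_ch, n = window.samples.shape
    df = pd.DataFrame(
        {
            "channel": np.repeat(np.arange(n_ch), n),
            "sample_index": np.tile(np.arange(n), n_ch),
            "value": window.samples.ravel(),
        }
    )
    df.to_csv(path, index=False)


def window_from_csv(path, t0: float = 0.0, sample_rate: int = SAMPLE_RATE) -> VoltageWindow:
    df = pd.read_csv(path)
    n_ch = int(df["channel"].max()) + 1
    n = int(df["sample_index"].max()) + 1
    samples = np.zeros((n_ch, n))
    samples[df["channel"].to_numpy(), df["sample_index"].to_numpy()] = df["value"].to_numpy()
    return VoltageWindow(t0=t0, samples=samples, sample_rate=sample_rate)


def truth_to_csv(window: VoltageWindow, path) -> None:
    pd.DataFrame({"channel": window.truth_channels, "time_s": window.truth_times}).to_csv(
        path, index=False
    )
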
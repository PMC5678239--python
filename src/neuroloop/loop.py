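"""Closed-loop orchestration, tracking metrics, and reports.

Runs the full pipeline on one simulated clock: frames are rendered from the
arm-mounted camera at the frame rate, hue-thresholded and quantized into
stimulation batches; the stimulated network half's firing rate rises for the
duration of each digitized signal; recording proceeds in 3-s / 3000-sample
windows; spikes feed the decaying activation vector; every 0.2 s the decoder
emits a motion command that moves the arm (or a homing step toward the
midpoint, when the target has been absent for a sustained run of frames);
and the camera view follows the arm.

Decisions are taken live at their 0.2-s ticks using events detected so far.
Detection thresholds inside a window use the channel statistics of the
window samples recorded up to the tick (an expanding, causal estimate of the
per-window statistics the offline decoder uses).

The tracking metric mirrors the experimental report: the time-weighted
fraction of the target-present observation period with the arm within 0.25
inch of the target, aggregated as mean +/- SD over seeds (seeds stand in for
replicate networks).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arm as arm_mod
from . import decoder as dec
from . import mea, scene, vision
from .arm import ArmState, CameraModel
from .decoder import ActivationState, MotionCommand, SpikeEvents
from .mea import MEALayout, NetworkConfig
from .scene import ABSENT, SceneConfig, TrajectorySpec
from .vision import Side


@dataclass(frozen=True)
class LoopConfig:
    """Full configuration of one closed-loop run.

    ``seed`` is the single source of randomness: it drives the network noise
    and spiking and (re-)seeds the scene's distractor field. ``tie_margin``
    here is the calibrated pipeline default (symmetric spontaneous activity
    should mostly read as "no clear side" and stop the arm); the bare
    ``decoder.classify`` keeps a near-zero margin.
    """

    scene: SceneConfig = SceneConfig()
    trajectory: TrajectorySpec | None = None  # None -> full-range triangle sweep
    network: NetworkConfig = NetworkConfig()
    # decoder
    beta: float = dec.DEFAULT_BETA
    reference_level: float = 2.0
    accept_distance: float | None = None  # None -> template norm
    tie_margin: float = 2.0
    threshold_mult: float = 3.0
    refractory: float = dec.DEFAULT_REFRACTORY
    two_sided_detection: bool = True
    contralateral: bool = True
    # vision
    hue_center: float = 0.0
    hue_tol: float = 10.0
    sat_min: float = 0.5
    val_min: float = 0.3
    quantum: int = vision.DEFAULT_QUANTUM
    max_signals_per_frame: int = 4
    # timing
    decision_period: float = dec.DECISION_PERIOD
    frame_period: float = 0.1
    window_duration: float = mea.WINDOW_S
    duration: float = 120.0
    # arm / camera
    arm_speed: float = 0.45  # calibrated: overshoot from 1-s signal persistence scales with speed
    arm_range: float = arm_mod.DEFAULT_RANGE
    field_of_view: float = arm_mod.DEFAULT_FOV
    homing_enabled: bool = True
    homing_patience: int = arm_mod.DEFAULT_HOMING_PATIENCE
    min_target_pixels: int = 2000
    # metrics
    tolerance: float = 0.25  # inches
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trajectory is None:
            object.__setattr__(self, "trajectory", scene.triangle_sweep(5.0, self.duration))
        if self.duration < self.window_duration:
            raise ValueError("duration must cover at least one recording window")
        spb = self.decision_period * self.network.sample_rate
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("decision_period must be an integer number of samples")
        ratio = self.window_duration / self.decision_period
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window_duration must be a multiple of decision_period")
        if self.max_signals_per_frame < 1:
            raise ValueError("max_signals_per_frame must be at least 1")


def default_config(duration: float = 120.0, seed: int = 0, **overrides) -> LoopConfig:
    """The calibrated default run: full-range sweep, spontaneous baseline on."""
    traj = overrides.pop("trajectory", scene.triangle_sweep(5.0, duration))
    return LoopConfig(duration=duration, seed=seed, trajectory=traj, **overrides)


def ideal_config(
    target_position: float = -3.0, duration: float = 30.0, seed: int = 0, **overrides
) -> LoopConfig:
    """Evoked-only network and a static target: a near-deterministic surrogate.

    With zero spontaneous baseline the only non-stimulus events are rare
    noise crossings; a wide tie margin keeps those from moving the arm, so
    the arm moves only under genuine visual drive.
    """
    traj = overrides.pop("trajectory", scene.static_target(target_position, duration))
    return LoopConfig(
        duration=duration,
        seed=seed,
        trajectory=traj,
        network=mea.ideal_network_config(seed=seed),
        tie_margin=overrides.pop("tie_margin", 5.0),
        **overrides,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class TrackingReport:
    """Per-tick trace of the run and its within-tolerance summary."""

    times: np.ndarray
    target_positions: np.ndarray  # NaN while the target is absent
    arm_positions: np.ndarray
    tolerance: float
    within_tolerance_fraction: float

    @property
    def errors(self) -> np.ndarray:
        return np.abs(self.arm_positions - self.target_positions)

    def to_dict(self) -> dict:
        return {
            "tolerance_inches": self.tolerance,
            "within_tolerance_fraction": self.within_tolerance_fraction,
            "n_ticks": int(len(self.times)),
            "n_target_present_ticks": int(np.isfinite(self.target_positions).sum()),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class LoopResult:
    config: LoopConfig
    report: TrackingReport
    decisions: pd.DataFrame  # t, d_left, d_right, command, homing, arm_pos, target_pos
    stimuli: pd.DataFrame  # frame_index, t, s0..s4, left3, right3, side, count, white
    n_spikes_detected: int
    n_spikes_injected: int

    @property
    def arm_trajectory(self) -> pd.DataFrame:
        df = self.decisions[["t", "arm_pos", "command"]].copy()
        df.columns = ["t", "position_inches", "last_command"]
        df["position_quantized"] = [
            arm_mod.quantize_position(p, self.config.tolerance) for p in df["position_inches"]
        ]
        return df


def tracking_fraction(
    arm_traj: np.ndarray | pd.DataFrame,
    target_traj: np.ndarray | pd.DataFrame,
    tolerance: float = 0.25,
) -> float:
    """Fraction of target-present time with |arm - target| < tolerance.

    Accepts matching (t, position) tables or bare position arrays on a
    shared time base (uniform ticks, so the time average is the tick mean).
    Absent-target ticks (NaN target) are excluded from the average.
    """
    if isinstance(arm_traj, pd.DataFrame):
        t_a, arm = arm_traj.iloc[:, 0].to_numpy(), arm_traj.iloc[:, 1].to_numpy()
    else:
        t_a, arm = None, np.asarray(arm_traj, dtype=float)
    if isinstance(target_traj, pd.DataFrame):
        t_t, tgt = target_traj.iloc[:, 0].to_numpy(), target_traj.iloc[:, 1].to_numpy()
    else:
        t_t, tgt = None, np.asarray(target_traj, dtype=float)
    if len(arm) != len(tgt):
        raise ValueError("arm and target trajectories must share a time base")
    if t_a is not None and t_t is not None and not np.allclose(t_a, t_t):
        raise ValueError("arm and target trajectories must share a time base")
    present = np.isfinite(tgt)
    if not present.any():
        return float("nan")
    return float((np.abs(arm[present] - tgt[present]) < tolerance).mean())


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------


def _derived_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] & 0x7FFFFFFF)


class _FrameEncoder:
    """Per-frame vision pipeline with incremental thresholding.

    Produces exactly ``threshold_hue(rgb_to_hsv(render_frame(scene, offset)))``
    for every offset: the static background's mask is computed once, and each
    frame re-thresholds only the pixel rows/columns the target rectangle
    occupies (the only pixels that differ from the background). Equivalence
    with the full per-frame pipeline is asserted in the test suite.
    """

    def __init__(self, scn: SceneConfig, cfg: "LoopConfig") -> None:
        self.scene = scn
        self.cfg = cfg
        bg = scene.render_frame(scn, ABSENT)
        self.bg_mask = vision.threshold_hue(
            vision.rgb_to_hsv(bg), cfg.hue_center, cfg.hue_tol, cfg.sat_min, cfg.val_min
        )

    def encode(self, offset: float | None) -> tuple[vision.StripSums, vision.StimulusBatch]:
        cfg = self.cfg
        mask = self.bg_mask
        if offset is not ABSENT:
            frame = scene.render_frame(self.scene, offset)
            scn = self.scene
            w, h = scn.frame_width, scn.frame_height
            center = w / 2.0 + float(offset)
            c0 = max(int(round(center - scn.target_width / 2.0)), 0)
            c1 = min(c0 + scn.target_width, w)
            r0 = (h - scn.target_height) // 2
            r1 = r0 + scn.target_height
            patch = vision.threshold_hue(
                vision.rgb_to_hsv(frame[r0:r1, c0:c1]),
                cfg.hue_center, cfg.hue_tol, cfg.sat_min, cfg.val_min,
            )
            mask = self.bg_mask.copy()
            mask[r0:r1, c0:c1] = patch
        sums = vision.strip_sums(mask)
        return sums, vision.stimulus_from_sums(sums, cfg.quantum)


def run_loop(cfg: LoopConfig) -> LoopResult:
    """Execute one closed-loop run; bit-reproducible for a fixed config."""
    fs = cfg.network.sample_rate
    spb = int(round(cfg.decision_period * fs))  # samples per decision block
    wn = int(round(cfg.window_duration * fs))  # samples per window
    n_ticks = int(round(cfg.duration / cfg.decision_period))
    n_frames = int(round(cfg.duration / cfg.frame_period))
    tick_of_frame = np.floor(
        np.arange(n_frames) * cfg.frame_period / cfg.decision_period + 1e-9
    ).astype(int)

    layout = mea.make_layout()
    scn = replace(cfg.scene, seed=_derived_seed(cfg.seed, 7))
    net = replace(cfg.network, seed=cfg.seed)
    refs = dec.default_references(layout, cfg.reference_level, cfg.accept_distance)
    cam = CameraModel(field_of_view=cfg.field_of_view, frame_width=scn.frame_width)
    encoder = _FrameEncoder(scn, cfg)
    arm = ArmState(position=0.0, speed=cfg.arm_speed, range=cfg.arm_range)
    state = ActivationState.zeros(beta=cfg.beta)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))

    active_stims: list[tuple[float, vision.StimulusBatch]] = []
    absent_streak = 0
    window_buf = np.zeros((layout.n_channels, wn))
    last_event_time = np.full(layout.n_channels, -np.inf)
    n_detected = 0
    n_injected = 0

    stim_rows: list[dict] = []
    dec_rows: list[dict] = []
    tick_times = np.empty(n_ticks)
    arm_positions = np.empty(n_ticks)
    target_positions = np.empty(n_ticks)

    frame_idx = 0
    for j in range(n_ticks):
        t_tick = (j + 1) * spb / fs  # same arithmetic as sample times

        # --- vision: frames falling in this decision interval -------------
        while frame_idx < n_frames and tick_of_frame[frame_idx] == j:
            f_t = frame_idx * cfg.frame_period
            pos = scene.sample_trajectory(cfg.trajectory, f_t)
            offset = arm_mod.view_offset(cam, arm, pos)
            sums, stim = encoder.encode(offset)
            if stim.count > cfg.max_signals_per_frame:
                stim = vision.StimulusBatch(stim.side, cfg.max_signals_per_frame)
            seen = sums.total >= cfg.min_target_pixels
            absent_streak = 0 if seen else absent_streak + 1
            if stim.side is not Side.NONE:
                active_stims.append((f_t, stim))
            row = vision.stimulus_record(frame_idx, sums, stim)
            row["t"] = f_t
            row["white"] = sums.total
            stim_rows.append(row)
            frame_idx += 1

        # --- network: simulate this block of samples ----------------------
        g0 = j * spb  # global index of the block's first sample
        t0_block = g0 / fs
        active_stims = [
            (ts, s) for ts, s in active_stims if ts + net.evoked_duration > t0_block
        ]
        rates = mea.rate_matrix(net, layout, active_stims, t0_block, spb)
        block, tr_ch, _ = mea.sample_block(rng, net, rates)
        n_injected += len(tr_ch)
        pos_in_win = g0 % wn
        window_buf[:, pos_in_win : pos_in_win + spb] = block
        filled = pos_in_win + spb

        # --- detection against the window-so-far statistics ---------------
        stats = dec.channel_stats(window_buf[:, :filled])
        events = dec.detect_crossings(
            block,
            stats,
            t_start=t0_block,
            sample_rate=fs,
            threshold_mult=cfg.threshold_mult,
            refractory=cfg.refractory,
            two_sided=cfg.two_sided_detection,
            last_event_time=last_event_time,
        )
        n_detected += len(events)

        # --- activation and classification --------------------------------
        state = dec.apply_events_chronologically(state, events, t_tick)
        d_left, d_right = dec.template_distances(state, refs)
        cmd = dec.classify(state, refs, cfg.tie_margin, cfg.contralateral)

        # --- arm -----------------------------------------------------------
        homing = cfg.homing_enabled and absent_streak >= cfg.homing_patience
        if homing:
            arm = arm_mod.homing_step(arm, absent_streak, cfg.homing_patience, cfg.decision_period)
        else:
            arm = arm_mod.apply_command(arm, cmd, cfg.decision_period)

        tgt = scene.sample_trajectory(cfg.trajectory, min(t_tick, cfg.duration))
        tick_times[j] = t_tick
        arm_positions[j] = arm.position
        target_positions[j] = np.nan if tgt is ABSENT else tgt
        dec_rows.append(
            {
                "t": t_tick,
                "d_left": d_left,
                "d_right": d_right,
                "command": cmd.value,
                "homing": homing,
                "arm_pos": arm.position,
                "target_pos": target_positions[j],
            }
        )

    frac = tracking_fraction(arm_positions, target_positions, cfg.tolerance)
    report = TrackingReport(
        times=tick_times,
        target_positions=target_positions,
        arm_positions=arm_positions,
        tolerance=cfg.tolerance,
        within_tolerance_fraction=frac,
    )
    return LoopResult(
        config=cfg,
        report=report,
        decisions=pd.DataFrame(dec_rows),
        stimuli=pd.DataFrame(stim_rows),
        n_spikes_detected=n_detected,
        n_spikes_injected=n_injected,
    )


def run_many(cfg: LoopConfig, seeds: list[int] | int) -> dict:
    """Replicate a run over seeds (stand-ins for replicate networks).

    Returns per-seed within-tolerance fractions with their mean and SD, and
    the individual reports.
    """
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    results = [run_loop(replace(cfg, seed=int(s))) for s in seeds]
    fractions = np.array([r.report.within_tolerance_fraction for r in results])
    return {
        "seeds": list(map(int, seeds)),
        "fractions": fractions,
        "mean": float(fractions.mean()),
        "sd": float(fractions.std(ddof=1)) if len(fractions) > 1 else 0.0,
        "results": results,
    }


def spontaneous_bias_experiment(cfg: LoopConfig) -> float:
    """Net signed arm displacement with no target and homing disabled.

    Probes the bias produced by uneven spontaneous activity between the two
    hemispheres: with symmetric baselines the displacement is symmetric
    around zero across seeds; a hemisphere with higher baseline activity
    pulls the arm toward the side its dominance maps to.
    """
    absent = replace(
        cfg.trajectory, absent_windows=((0.0, cfg.trajectory.duration),)
    )
    quiet = replace(cfg, trajectory=absent, homing_enabled=False)
    result = run_loop(quiet)
    return float(result.report.arm_positions[-1])


# ---------------------------------------------------------------------------
# Config and result I/O
# ---------------------------------------------------------------------------


def config_to_dict(cfg: LoopConfig) -> dict:
    d = asdict(cfg)
    d["scene"]["background_palette"] = [list(c) for c in cfg.scene.background_palette]
    if cfg.trajectory.kind == "piecewise":
        d["trajectory"]["positions"] = [list(p) for p in cfg.trajectory.positions]
    else:
        d["trajectory"]["positions"] = list(cfg.trajectory.positions)
    d["trajectory"]["absent_windows"] = [list(w) for w in cfg.trajectory.absent_windows]
    return d


def config_from_dict(d: dict) -> LoopConfig:
    d = dict(d)
    sc = d.pop("scene", {})
    if "background_palette" in sc:
        sc["background_palette"] = tuple(tuple(c) for c in sc["background_palette"])
    tr = d.pop("trajectory", None)
    nw = d.pop("network", {})
    traj = None
    if tr is not None:
        pos = tr["positions"]
        if tr["kind"] == "piecewise":
            pos = tuple(tuple(p) for p in pos)
        else:
            pos = tuple(pos)
        traj = TrajectorySpec(
            kind=tr["kind"],
            duration=tr["duration"],
            positions=pos,
            absent_windows=tuple(tuple(w) for w in tr.get("absent_windows", ())),
        )
    return LoopConfig(scene=SceneConfig(**sc), trajectory=traj, network=NetworkConfig(**nw), **d)


def load_config(path: str | Path) -> LoopConfig:
    """Load a LoopConfig from a YAML or JSON document."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_dict(data)


def save_config(cfg: LoopConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def write_result(result: LoopResult, out_dir: str | Path) -> None:
    """Write decisions/arm/stimulus CSVs and the tracking report JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.decisions.to_csv(out / "decisions.csv", index=False)
    result.arm_trajectory.to_csv(out / "arm_trajectory.csv", index=False)
    result.stimuli.to_csv(out / "stimuli.csv", index=False)
    result.report.to_json(out / "tracking_report.json")


def plot_tracking(result: LoopResult, path: str | Path) -> None:
    """Arm-versus-target position plot for one run (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = result.report
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(rep.times, rep.target_positions, label="target", lw=1.5)
    ax.plot(rep.times, rep.arm_positions, label="arm", lw=1.0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position (inches)")
    ax.legend(loc="upper right")
    frac = rep.within_tolerance_fraction
    ax.set_title(f"within {rep.tolerance}\" of target: {100 * frac:.1f}% of target-present time")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
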
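# Methods

## Scope and intent

`neuroloop` models a closed-loop neurorobotic system in which a cultured
neuronal network on a 60-electrode MEA, segmented into two hemispheres,
mediates between a camera watching a colored target and a one-dimensional
robot arm carrying that camera. Everything biological is replaced by an
explicit stochastic model; everything algorithmic (visual encoding,
spike detection, activation-vector decoding, actuation, homing) is
implemented as specified behavior and tested against independent oracles.
The simulation is deterministic given its configuration, including the seed.

## Visual encoding

Frames are `(height, width, 3)` uint8 arrays. The default scene is 640×480
with a 200×150 px solid-red target over a static tiled background of muted
colors; a configurable fraction (default 0.002) of background pixels is
independently recolored to the target hue, standing in for incidental red
objects in the field of view (distractors are i.i.d. per-pixel, not a
coherent blob — a deliberate simplification).

Thresholding is on circular hue distance (default tolerance 10°) with
saturation ≥ 0.5 and value ≥ 0.3 gates; the gates reject achromatic and
dark pixels whose hue coordinate is meaningless. The mask is split into
five vertical strips (wider strips leftmost when the width is not divisible
by 5 — any fixed rule works; this one is asserted in tests). The
left-minus-right comparison uses the literal overlapping groups (strips
0–2 vs 2–4), whose shared middle strip cancels in the difference; a
`disjoint` switch compares strips {0,1} vs {3,4} and produces identical
stimuli. Each full 500-px difference (the quantum) maps to one stimulation
signal, `count = ⌊|Δ|/500⌋`, delivered contralaterally.

**Target size.** The default target (200 px) is wider than one strip
(128 px). A target narrower than the middle strip produces no differential
signal until it leaves that strip entirely — a dead zone of about ±0.8 inch
at the default optics (64 px/inch), which would make quarter-inch tracking
impossible. With the wide target, a 1-column shift moves 2×150 px of
difference, so the quantum corresponds to ~0.03 inch of target motion:
the loop responds to sub-quarter-inch displacements, consistent with the
system's reported responsiveness granularity of 0.25 inch.

## Network model

The 60 channels sit on an 8×8 grid without corners; columns 0–3 are the
LEFT hemisphere, 4–7 RIGHT (30 channels each). Each channel's spike train
is an inhomogeneous Poisson process sampled per 1-ms bin
(`p = 1 − e^{−rate·dt}`, at most one spike per bin), riding on Gaussian
noise (SD 1) as single-sample deflections of amplitude 6 (a biphasic
option exists, default off, to keep ground truth exactly countable).

Rates: `rate = baseline(hemisphere) + gain × Σ active signal counts`, where
a signal delivered at `t_s` is active on its hemisphere for
`evoked_duration = 1 s` (the length of the digitized synaptic stimulus).
Stimulation never affects the opposite hemisphere, mirroring the
confinement of responses in the severed culture. Defaults: baseline
2 spikes/s/channel per hemisphere, gain 0.3 spikes/s/channel per active
signal, with stimulation delivery capped at 4 signals per frame (a bounded
stimulator-throughput assumption).

**Why gain 0.3 and the cap.** At 10 frames/s with 1-s signals, a sustained
k-signal-per-frame drive keeps ~10k signals concurrently active. The
activation equilibrium per channel is roughly `A ≈ (rate + r_fp)/β` (with
`r_fp ≈ 2.7/s` of threshold false positives). For the classifier to accept
the driven state, `A` must stay inside the template acceptance ball:
`|A_driven − a| ≤ √(a² − A_rest²)` with template level `a = 2`. With the
cap at 4 and gain 0.3, `A` ranges over ≈1.5–3.3 across the full drive
range, inside the ball, while remaining well separated from the symmetric
rest state (`A_rest ≈ 0.9`). Larger gains push strong drives outside the
acceptance ball and read as STOP exactly when correction is most needed.

No bursts, plasticity, latency, or waveform structure are modeled: the
decoder consumes only threshold crossings, so the rate-level abstraction is
sufficient for closed-loop behavior. Consequences: passing tests show the
*pipeline* reproduces the system's behaviors under Poisson-like activity;
they say nothing about real cultures' burst dynamics, nonstationarity, or
electrode artifacts.

## Decoder

Spikes: |deviation from window mean| > 3 × window SD (positive-only
switch available), thinned by a 2-ms refractory gap so one deflection is
one event. Statistics are per 3-s window. On pure noise this yields a
binomial false-positive count with mean `3000 × 2(1−Φ(3)) ≈ 8.1` per
channel per window — an intrinsic property of SD-multiplier detection that
the calibration tests pin against the Gaussian-tail oracle. These false
positives act as a floor of symmetric background "activity" on both
hemispheres.

Activation: decay-then-increment recursion with `β = 5 s⁻¹` (time constant
equal to the 0.2-s decision period; the decay constant is not dictated by
the system being modeled, so it is config-exposed). The recursion is tested
to 1e-9 against the shot-noise closed form `A_n(t) = Σ_k e^{−β(t−t_k)}`.

Templates: level `a = 2` on one hemisphere's 30 channels, 0 elsewhere;
acceptance distance `δ = ‖L‖ = a√30`, so the all-zero rest state lies
exactly on the acceptance boundary. `calibrate_reference_level` recovers a
level from observed activations under sustained drive. The classifier
STOPs when neither template is accepted *or* when the two distances are
within a tie margin. Since `d_L² − d_R² = 2a(Σ_right A − Σ_left A)`, the
winning template is simply the hemisphere with the larger activation sum,
and the tie margin is a dead band on that contrast.

`classify()` defaults to a near-zero tie margin (pure argmin with an exact
tie rule). The pipeline default is `tie_margin = 2.0` (and 5.0 in the
evoked-only configuration): symmetric spontaneous activity produces
distance fluctuations of order 1, and the margin converts those into STOP
instead of a random walk of the arm. This is the package's reading of
"approximates one of the fixed vectors": both a proximity and a
distinctness requirement.

## Arm, camera, homing

Constant-speed kinematics clamped to ±10 inch; camera FOV 10 inch centered
on the arm (64 px/inch at the default frame width). The loop's default arm
speed is 0.45 inch/s. This is the main calibrated parameter: each
stimulation signal persists 1 s, so after the arm crosses the target the
stale contralateral drive keeps pushing it for up to ~1 s, and the
overshoot amplitude is proportional to arm speed. At 1 inch/s the
oscillation is ±0.3–0.6 inch (≈41% within a quarter inch); at 0.45 inch/s
the loop holds ≈79–80%, comparable to the reported accuracy of the modeled
system, while still tracking the default sweep (0.17 inch/s) with margin.

Homing: after 10 consecutive frames (1 s) in which the thresholded mask
contains fewer than `min_target_pixels = 2000` white pixels, the arm steps
toward the midpoint at its speed, stopping exactly at 0, until the target
reappears. Absence is thus detected from the vision output, not from
oracle knowledge of the scene.

## Scheduling and numerics

One shared clock: frames every 0.1 s, decisions every 0.2 s, recording
windows tiling the run in 3-s blocks (15 decisions per window). Stimuli
take effect at their frame time; an evoked tail may extend into the next
window. Decisions are taken live at their ticks using events detected so
far; within a window the detection threshold uses the channel statistics
of the samples recorded up to the tick (an expanding, causal estimate of
the same per-window statistics the offline `decode_window` uses — the two
agree in distribution once a few hundred samples have accumulated, and
detection of 6σ deflections is insensitive to the residual difference).
Sample, tick, and frame times are derived from integer indices to keep
boundary comparisons exact; the activation update tolerates sub-nanosecond
backsteps at shared boundaries.

The loop's per-frame vision stage uses an incremental encoder: the static
background's mask is thresholded once and only the columns occupied by the
target are re-thresholded per frame. This is exactly equal to running the
full pipeline on every rendered frame (asserted in the test suite) and is
what makes a 120-s run take seconds rather than minutes.

Problem sizes used by the shipped experiments: 120-s runs × 5 seeds for
the tracking benchmark; 30 s for static-target convergence; 60 s for the
removal/homing scenario; 20 s × 20 seeds for the spontaneous-bias
experiments.

## Known limitations

- Distractors are i.i.d. pixels, not a moving partially-red object; the
  strip difference they induce is zero-mean with SD ≈ 25 px, far below the
  500-px quantum, so they never flip a stimulus on their own.
- The arm is kinematic (no inertia, backlash, or variable speed) and
  motion is strictly one-dimensional.
- The biological headline number came from living networks; the simulated
  benchmark shows the *pipeline* can achieve that accuracy under the
  stated noise model, not that the model reproduces culture physiology.
- Spontaneous-activity asymmetry produces an essentially deterministic
  drift to the dominant side's rail, a stylized version of the reported
  bias; real networks drift more slowly because their asymmetries are
  smaller and nonstationary.
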
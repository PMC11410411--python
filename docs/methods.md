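# Methods

This note documents the models, conventions and numerical choices behind
`gaitdecomp`, and what the synthetic cohort does and does not emulate.

## Decomposition index

**Pause criterion.** A joint is paused at a frame when |angular velocity| <
`pause_threshold_fraction` × (peak |angular velocity| within the current
cycle). The reference ("baseline") velocity is deliberately the *per-cycle,
per-joint peak*: this makes the criterion invariant to amplitude scaling of
a trajectory and lets slow and fast walkers be treated identically. Other
readings of "baseline" (trial-level mean or reference-condition peak) would
couple cycles together; the per-cycle peak is the most local, assumption-free
choice. Default fraction: 0.05.

**Frozen-joint floor.** A purely relative threshold is degenerate when the
peak velocity itself approaches zero — a fully frozen joint would never
count as paused. If the per-cycle peak is below `velocity_floor` (default
1 deg/s) the joint is declared paused for the entire cycle.

**Index.** `D = 100 · #(exactly one of the pair paused) / #(at least one
moving)`. Both-paused frames are excluded from numerator **and**
denominator: a frame in which neither joint moves carries no information
about interjoint sequencing. This convention is what makes the two analytic
boundary cases exact under sampling: identical in-phase trajectories give
`D = 0`, and a frozen joint against a moving one gives `D = 100` even
though the moving joint necessarily spends a frame or two below threshold
at each velocity zero-crossing (with a 5% threshold and 120 samples/cycle,
the sub-threshold band at a sinusoidal reversal is ≈ 0.1 rad ≈ 2 samples).
Normalizing by the full cycle length instead would cap the frozen-joint
case at ≈ 98%. When both joints are paused for the whole cycle the index is
defined as 0. `D` is symmetric in the pair, bounded in [0, 100], invariant
to scaling or offsetting either trajectory, and equal to direct per-frame
enumeration (both properties are tested).

**Natural dwell.** Any periodic joint angle has ≥ 2 velocity zero-crossings
per cycle, so even perfectly coordinated gait shows a nonzero index — a few
frames of dwell per reversal, ≈ 5–10% per pair for comfortable walking.
Measured indices therefore track *injected* pause fractions additively on
top of this floor. Exact ±2-point recovery of an injected fraction is only
meaningful on trajectories without reversals (constant-velocity sweeps),
and that is how the recovery guarantee is stated and tested; on gait-shaped
cycles the guarantee is monotone recovery and additivity over the baseline.

**Velocity estimation.** Angles are low-pass filtered (zero-phase 4th-order
Butterworth, `filter_cutoff` 6 Hz default) and differentiated with central
differences (one-sided at the ends). Differentiating unfiltered marker-
derived angles would fragment pause windows with noise spikes. No minimum
pause duration is imposed; fragmentation control is left to the filter.

## Event detection and cycles

Foot contact = local maximum of the heel marker's position along the
direction of progression *relative to the sacrum*; toe-off = local minimum
of the relative toe position (coordinate-based detection; no force data).
The progression axis is the principal horizontal direction of sacrum
displacement, so recordings need not be axis-aligned. Peaks are picked on
6 Hz-filtered signals with a 0.4 s minimum separation. A cycle is the
half-open frame interval between consecutive same-side contacts; partial
strides before the first and after the last contact are discarded; cycles
outside 0.4–3.0 s are flagged. Exactly one toe-off is kept per cycle (the
deepest toe-back minimum inside it).

## Kinematics and spatiotemporal metrics

Angles come from a planar model in the progression–vertical plane: hip =
thigh tilt from vertical, knee = thigh–shank angle, ankle = foot pitch
minus the shank perpendicular (dorsiflexion positive). Frontal/transverse
rotations are out of scope. Per-cycle maxima are reported with
plantarflexion as a positive magnitude (`|min ankle|` when the minimum is
negative, else 0).

Gait velocity = filtered sacrum horizontal path length / cycle duration.
Step length and width = anterior and mediolateral heel-to-heel distances at
each foot contact within the cycle, both sides' steps averaged (the
measurement side for step measures is a convention; averaging both steps is
the least arbitrary). Double support = percentage of cycle frames with both
feet in stance, reconstructed from both sides' contact/toe-off sequences;
it is NaN (flagged) when contralateral events are missing. Foot clearance =
peak swing toe height minus the mean toe height over foot-flat stance
frames (|foot pitch| < 10°, falling back to the lowest stance quartile) —
a peak-height definition, chosen because minimum-clearance definitions
yield values an order of magnitude smaller than the 0.16–0.19 m range this
metric is meant to occupy.

## Synthetic cohort

The generator emulates a motion-capture study of foot-drop gait: 16
participants, four conditions (no assistance, AFO, elastic dorsiflexion
harness, full harness), 3 trials × 4 strides per condition, 100 Hz,
self-selected speed 0.65 ± 0.25 m/s (clipped to the 0.24–1.13 m/s range of
such cohorts), ten of sixteen paretic on the left.

**Templates.** Each joint follows a fixed ≤ 3-harmonic waveform (foot
contact at phase 0): hip — skewed cosine, peak flexion at ~97% of the
cycle, peak extension at ~53%; knee — skewed wave, full extension at
contact, swing flexion peak at ~72%; ankle — the knee waveform negated and
re-phased, plantarflexion trough at pre-swing (~62%), dorsiflexion peak in
swing. Waveforms are affinely rescaled so the sampled per-cycle extrema
equal the requested maxima exactly. Two deliberate template properties:
reversal sharpness is tuned so a healthy cycle shows the 5–10% decomposition
window characteristic of comfortable walking, and the three joints'
reversal phases are mutually offset so their natural dwells rarely
coincide. The stance-phase knee flexion bump of able-bodied gait is omitted
to keep each joint at two reversals per cycle.

**Condition effects.** Participant-level baselines (speed, four ROM maxima,
three pair-level pause fractions, step width) are drawn once per
participant from the no-assistance distributions (means/SDs of the emulated
population); condition effects are added as mean shifts; small trial-level
jitters are drawn per trial. Pair-level pause targets are converted to
per-joint injected pauses by solving `p_h+p_k = D_hk, p_h+p_a = D_ha,
p_k+p_a = D_ka` (clipped to [0, 0.24]) and placing the three pause windows
at disjoint cycle phases (hip 0.30, knee 0.55, ankle 0.05).

**Pause injection** freezes the joint over `round(f·n)` samples starting at
the placement phase and traverses the remaining trajectory at a uniformly
increased rate, preserving cycle duration and periodic endpoints (velocity
is exactly zero inside the window).

**Forward kinematics.** The pelvis advances at constant speed along +X with
legs offset laterally by half the step width and phase-shifted by half a
cycle; hip→knee→ankle→heel/toe positions follow from segment lengths
(defaults 0.41/0.43/0.20 m) and the sagittal angles; pelvis height is set
so the lowest foot-marker sample grazes the floor. There is **no ground
contact constraint**: the stance foot translates with the body rather than
sticking to the floor. Consequently double support comes out low
(~12–14% vs ~30% in slow pathological gait), step length is set by leg
geometry rather than speed × time, and foot contact must be *defined*
kinematically — as the instant the heel is farthest forward relative to
the sacrum (likewise toe-off, toe farthest back). Ground-truth events are
computed from the noise-free markers under exactly that definition, which
is also what the detector estimates from noisy data.

**Noise.** Additive i.i.d. Gaussian noise on marker coordinates (default
2 mm). One side effect worth knowing: per-cycle *maxima* of noisy angle
series read high by ~1–3° (extreme-value inflation), so the noisy cohort's
mean dorsiflexion exceeds the configured population mean; the inflation is
common to all conditions and leaves contrasts intact. Parameter-recovery
guarantees are stated for noise-free cohorts.

**Determinism.** Each participant consumes an independent child stream of
the master `SeedSequence`; a fixed seed reproduces the cohort bit for bit.

**What passing tests do not show.** The generator is planar, template-
driven and noise-stationary; it contains no circumduction or hip-hiking
compensation, no ground-reaction mechanics, no marker dropout or soft-
tissue artifact, and its condition effects are pure mean shifts. Tests
against it validate the *measurement chain*, not clinical effect sizes.

## Statistics

Averaging: unweighted mean over cycles within trial, then over trials
within condition — one value per participant × condition. The condition
comparison is a one-way ANOVA treating each (participant, condition) mean
as an independent cell, giving df (3, 60) for 16 × 4 — the convention of
the emulated study design; a repeated-measures variant (df (3, 45)) is
available behind `repeated_measures=True` but is not the default. Partial
η² = SS_effect/(SS_effect+SS_error), labelled small/medium/large at
0.02/0.13/0.26. Tukey HSD (statsmodels) provides the pairwise comparisons;
table significance markers require the omnibus test to pass at α first.
The KS normality check uses the sample's own mean/SD (estimated
parameters make it conservative, the Lilliefors caveat) and is advisory —
the pipeline proceeds parametrically. Comfort scores are compared with
paired t-tests at a Bonferroni-adjusted α of 0.03 (kept as the emulated
study's printed value; 0.05/3 would be 0.017 — configurable via
`comfort_alpha`).

## Problem sizes and degenerate inputs

Default test/demo scales: recovery tests use 3-participant noise-free
cohorts; the structural check runs the full 16 × 4 × 3 cohort once
(≈ 9 s end to end); the ANOVA null simulation uses 1000 replicates of a
16 × 4 table. Degenerate inputs are defined rather than left to chance:
zero requested maxima → constant-zero series; zero-variance samples →
degenerate flags (KS, paired t); all-joints-frozen → index 0; gaps longer
than 10 frames (100 ms) or touching the trial edge → data-quality error
rather than silent bridging.

## Known limitations

C3D files are not read or written (binary format; text formats CSV and TRC
are supported). Turning gait, treadmill protocols and force-based event
detection are out of scope. The ANOVA default ignores the within-subject
correlation by design (to match the emulated reporting convention);
statistical power statements based on it do not transfer to
repeated-measures designs.
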
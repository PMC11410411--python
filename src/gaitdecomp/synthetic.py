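"""Synthetic foot-drop gait generator.

Produces seeded, ground-truth-annotated walking trials (sagittal joint
angles plus planar marker trajectories) that emulate a motion-capture study
of foot-drop gait under four walking conditions: no assistance, a posterior
leaf-spring AFO, an elastic dorsiflexion-assist harness, and the same
harness in its full hip+dorsiflexion configuration. The emulated population
walks at 0.65 +/- 0.25 m/s with reduced sagittal range of motion on one
(paretic) side; condition effects shift gait speed, the four kinematic
maxima and the interjoint pause structure.

Joint-angle templates
---------------------
Each joint follows a fixed low-order Fourier waveform over the gait cycle
(foot contact at phase 0), rescaled so its per-cycle extrema equal the
requested maxima:

* hip: near-cosine with a mild second harmonic; peak flexion in terminal
  swing (~97% of the cycle), peak extension mid-stance (~53%).
* knee: skewed three-harmonic wave; full extension at contact, swing
  flexion peak at ~72%.
* ankle: the knee waveform negated and re-phased; plantarflexion trough at
  pre-swing (~62%), dorsiflexion peak in swing.

The harmonic coefficients are fixed in code. Reversal sharpness was chosen
so that a healthy-template cycle shows the 5-10% decomposition-index window
reported for comfortable healthy walking, and the reversal phases of the
three joints are mutually offset so simultaneous pauses are rare.

Pathological interjoint decomposition is injected explicitly: a joint's
motion is frozen for a prescribed fraction of the cycle while the rest of
its trajectory is uniformly time-warped, preserving cycle duration and
endpoint continuity.

Markers come from a planar two-leg forward-kinematic chain: the pelvis
advances at constant speed along +X, legs are phase-shifted by half a
cycle, and sacrum/hip/knee/ankle/heel/toe markers follow from the segment
lengths and sagittal angles. There is no ground-contact constraint; foot
contact is defined kinematically as the instant the heel is farthest
forward relative to the sacrum, and toe-off as the instant the toe is
farthest back (the same coordinate-based definitions the event detector
uses on real recordings).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .core import CONDITIONS, JOINTS, JointAngleSeries, TrialRecording, marker_name
from .exceptions import ConfigurationError, DomainError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TrialTruth",
    "generate_angle_cycle",
    "inject_pause",
    "angles_to_markers",
    "generate_cohort",
    "generate_comfort_scores",
    "null_config",
]

TWO_PI = 2.0 * np.pi

# Frozen template coefficients (see module docstring).
_W_B, _W_C = -0.20, 0.15
_KNEE_SHIFT = 0.628
_ANKLE_SHIFT = 0.273
_HIP_SKEW = -0.10
_HIP_DC = 0.35
_HIP_AMP = 0.65

#: Nominal toe-off phase of the template (toe-back peak), as cycle fraction.
NOMINAL_TOEOFF_PHASE = 0.562

# Phase at which each joint's injected pause window starts (disjoint windows
# for pause fractions up to 0.24 per joint).
_PAUSE_PLACEMENT = {"hip": 0.30, "knee": 0.55, "ankle": 0.05}
_MAX_JOINT_PAUSE = 0.24


def _w(x: np.ndarray) -> np.ndarray:
    return np.sin(TWO_PI * x) + _W_B * np.sin(2 * TWO_PI * x) + _W_C * np.sin(3 * TWO_PI * x)


def _hip_shape(p: np.ndarray) -> np.ndarray:
    return _HIP_AMP * (np.cos(TWO_PI * p) + _HIP_SKEW * np.sin(2 * TWO_PI * p)) + _HIP_DC


def _knee_shape(p: np.ndarray) -> np.ndarray:
    return _w(p + _KNEE_SHIFT)


def _ankle_shape(p: np.ndarray) -> np.ndarray:
    return -_w(p - _ANKLE_SHIFT)


def _scaled_angles(phases: np.ndarray, maxima: dict[str, float]) -> np.ndarray:
    """(n, 3) hip/knee/ankle angles in degrees with sampled extrema matching ``maxima``."""
    hip = _hip_shape(phases)
    knee = _knee_shape(phases)
    ankle = _ankle_shape(phases)
    out = np.empty((phases.shape[0], 3))
    hmax = hip.max()
    out[:, 0] = hip * (maxima["hip"] / hmax) if hmax > 0 else 0.0
    kspan = knee.max() - knee.min()
    out[:, 1] = (knee - knee.min()) / kspan * maxima["knee"] if kspan > 0 else 0.0
    aspan = ankle.max() - ankle.min()
    total = maxima["dorsiflexion"] + maxima["plantarflexion"]
    if aspan > 0 and total > 0:
        sc = total / aspan
        out[:, 2] = sc * ankle + (maxima["dorsiflexion"] - sc * ankle.max())
    else:
        out[:, 2] = 0.0
    return out


def generate_angle_cycle(
    joint_maxima: dict[str, float],
    cycle_duration: float,
    sample_rate: float,
    side: str = "right",
) -> JointAngleSeries:
    """One gait cycle of sagittal joint angles for one leg.

    ``joint_maxima`` carries the requested per-cycle extrema in degrees:
    ``hip`` (peak flexion), ``knee`` (peak flexion), ``dorsiflexion`` and
    ``plantarflexion`` (both as positive magnitudes). The emitted series has
    ``round(cycle_duration * sample_rate)`` samples at phases i/n, tiles
    periodically, and its sampled extrema equal the requested maxima exactly.
    """
    if cycle_duration <= 0 or sample_rate <= 0:
        raise ConfigurationError(
            f"cycle_duration and sample_rate must be positive, got {cycle_duration}, {sample_rate}"
        )
    required = ("hip", "knee", "dorsiflexion", "plantarflexion")
    missing = [k for k in required if k not in joint_maxima]
    if missing:
        raise ConfigurationError(f"joint_maxima missing keys: {missing}")
    vals = {k: float(joint_maxima[k]) for k in required}
    if not all(np.isfinite(v) for v in vals.values()):
        raise ConfigurationError(f"joint maxima must be finite, got {vals}")
    if vals["dorsiflexion"] < 0 or vals["plantarflexion"] < 0:
        raise ConfigurationError("dorsiflexion and plantarflexion maxima must be >= 0")
    n = int(round(cycle_duration * sample_rate))
    if n < 4:
        raise ConfigurationError(f"cycle too short: {n} samples")
    phases = np.arange(n) / n
    return JointAngleSeries(sample_rate=sample_rate, angles={side: _scaled_angles(phases, vals)})


def _periodic_interp(y: np.ndarray, phases: np.ndarray) -> np.ndarray:
    n = y.shape[0]
    xp = np.arange(n + 1) / n
    fp = np.append(y, y[0])
    return np.interp(np.mod(phases, 1.0), xp, fp)


def inject_pause(
    series: JointAngleSeries,
    joint: str,
    fraction: float,
    placement: float = 0.0,
    side: str | None = None,
) -> JointAngleSeries:
    """Freeze one joint for ``fraction`` of the cycle, time-warping the rest.

    The pause window spans ``round(fraction * n)`` samples starting at cycle
    phase ``placement``; within it the joint's angle is constant (angular
    velocity exactly zero). Outside the window the original trajectory is
    traversed at a uniformly increased rate, so cycle duration and the
    periodic endpoints are unchanged. Other joints are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DomainError(f"pause fraction must be in [0, 1], got {fraction}")
    if not 0.0 <= placement <= 1.0:
        raise DomainError(f"placement must be in [0, 1], got {placement}")
    if side is None:
        if len(series.angles) != 1:
            raise DomainError("side must be given for a two-legged series")
        side = series.sides[0]
    if joint not in JOINTS:
        raise DomainError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    out = series.copy()
    n = series.n_samples
    m = int(round(fraction * n))
    if m == 0:
        return out
    col = JOINTS.index(joint)
    y = series.angles[side][:, col]
    if m >= n:
        out.angles[side][:, col] = _periodic_interp(y, np.array([placement]))[0]
        return out
    i0 = min(int(round(placement * n)), n - m)
    idx = np.arange(n, dtype=float)
    phases = np.empty(n)
    phases[:i0] = idx[:i0] / (n - m)
    phases[i0 : i0 + m] = i0 / (n - m)
    phases[i0 + m :] = (idx[i0 + m :] - m) / (n - m)
    out.angles[side][:, col] = _periodic_interp(y, phases)
    return out


def angles_to_markers(
    series: JointAngleSeries,
    segment_lengths: tuple[float, float, float] = (0.41, 0.43, 0.20),
    pelvis_speed: float = 0.65,
    step_width: float = 0.21,
    participant_id: str = "synthetic",
    condition: str = "no_assistance",
    paretic_side: str = "left",
    floor_margin: float = 0.005,
) -> TrialRecording:
    """Planar forward kinematics: sagittal angles -> marker trajectories.

    The pelvis advances at ``pelvis_speed`` along +X; each leg hangs from a
    hip joint offset laterally by half the step width. Heel and toe markers
    lie on the foot segment (25% / 75% of foot length from the ankle). The
    pelvis height is set so the lowest foot-marker sample sits
    ``floor_margin`` above the ground. If ``series`` holds a single leg its
    angles are used for both legs.
    """
    lt, ls, lf = segment_lengths
    if lt <= 0 or ls <= 0 or lf <= 0:
        raise ConfigurationError(f"segment lengths must be positive, got {segment_lengths}")
    n = series.n_samples
    rate = series.sample_rate
    t = np.arange(n) / rate
    markers: dict[str, np.ndarray] = {}

    sides = {"left": None, "right": None}
    for s in sides:
        sides[s] = series.angles.get(s, series.angles[series.sides[0]])

    rel: dict[str, np.ndarray] = {}
    zmin = np.inf
    for s, ang in sides.items():
        h = np.radians(ang[:, 0])
        k = np.radians(ang[:, 1])
        a = np.radians(ang[:, 2])
        knee = np.column_stack([lt * np.sin(h), np.zeros(n), -lt * np.cos(h)])
        shank_dir = np.column_stack([np.sin(h - k), np.zeros(n), -np.cos(h - k)])
        ankle = knee + ls * shank_dir
        psi = h - k + a  # foot pitch relative to ground, toes-up positive
        foot_dir = np.column_stack([np.cos(psi), np.zeros(n), np.sin(psi)])
        heel = ankle - 0.25 * lf * foot_dir
        toe = ankle + 0.75 * lf * foot_dir
        for base, arr in (("knee", knee), ("ankle", ankle), ("heel", heel), ("toe", toe)):
            rel[marker_name(base, s)] = arr
            zmin = min(zmin, float(arr[:, 2].min()))

    hip_height = -zmin + floor_margin
    x_pelvis = pelvis_speed * t
    markers["sacrum"] = np.column_stack([x_pelvis, np.zeros(n), np.full(n, hip_height)])
    for s in sides:
        y_off = step_width / 2.0 if s == "left" else -step_width / 2.0
        hip_pos = np.column_stack([x_pelvis, np.full(n, y_off), np.full(n, hip_height)])
        markers[marker_name("hip", s)] = hip_pos
        for base in ("knee", "ankle", "heel", "toe"):
            markers[marker_name(base, s)] = hip_pos + rel[marker_name(base, s)]

    rec = TrialRecording(
        participant_id=participant_id,
        condition=condition,
        sample_rate=rate,
        markers=markers,
        paretic_side=paretic_side,
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _table1_rom_means() -> dict[str, dict[str, float]]:
    return {
        "no_assistance": {"hip": 26.8, "knee": 35.7, "plantarflexion": 24.6, "dorsiflexion": 9.6},
        "afo": {"hip": 29.0, "knee": 37.0, "plantarflexion": 19.5, "dorsiflexion": 14.5},
        "newgait_dorsiflexion": {"hip": 28.5, "knee": 39.5, "plantarflexion": 26.5, "dorsiflexion": 14.3},
        "newgait_full": {"hip": 27.5, "knee": 36.2, "plantarflexion": 28.0, "dorsiflexion": 12.0},
    }


def _table1_rom_sds() -> dict[str, dict[str, float]]:
    return {
        "no_assistance": {"hip": 7.8, "knee": 12.8, "plantarflexion": 4.21, "dorsiflexion": 4.21},
        "afo": {"hip": 10.2, "knee": 10.6, "plantarflexion": 4.29, "dorsiflexion": 3.29},
        "newgait_dorsiflexion": {"hip": 8.2, "knee": 5.16, "plantarflexion": 7.23, "dorsiflexion": 5.2},
        "newgait_full": {"hip": 6.9, "knee": 7.28, "plantarflexion": 6.31, "dorsiflexion": 6.88},
    }


def _table2_pause_fractions() -> dict[str, dict[str, float]]:
    return {
        "hip_knee": {"no_assistance": 0.161, "afo": 0.217, "newgait_dorsiflexion": 0.115, "newgait_full": 0.108},
        "hip_ankle": {"no_assistance": 0.137, "afo": 0.202, "newgait_dorsiflexion": 0.122, "newgait_full": 0.147},
        "knee_ankle": {"no_assistance": 0.217, "afo": 0.258, "newgait_dorsiflexion": 0.151, "newgait_full": 0.184},
    }


def _condition_speed_means() -> dict[str, float]:
    return {"no_assistance": 0.65, "afo": 0.71, "newgait_dorsiflexion": 0.72, "newgait_full": 0.77}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the emulated study: 16 participants, 4 conditions,
    3 trials x 4 strides at 100 Hz, comfortable speed 0.65 +/- 0.25 m/s,
    paretic-side range-of-motion maxima and pair-level pause fractions per
    condition, and 2 mm marker noise.
    """

    n_participants: int = 16
    n_trials_per_condition: int = 3
    strides_per_trial: int = 4
    sample_rate: float = 100.0
    conditions: tuple[str, ...] = CONDITIONS
    speed_mean: float = 0.65
    speed_sd: float = 0.25
    condition_speed_means: dict[str, float] = field(default_factory=_condition_speed_means)
    rom_means: dict[str, dict[str, float]] = field(default_factory=_table1_rom_means)
    rom_sds: dict[str, dict[str, float]] = field(default_factory=_table1_rom_sds)
    healthy_maxima: dict[str, float] = field(
        default_factory=lambda: {"hip": 30.0, "knee": 60.0, "dorsiflexion": 15.0, "plantarflexion": 20.0}
    )
    pause_fractions: dict[str, dict[str, float]] = field(default_factory=_table2_pause_fractions)
    pause_between_sd: float = 0.03
    rom_trial_sd: float = 1.0
    speed_trial_sd: float = 0.02
    noise_sd_marker: float = 0.002
    noise_sd_angle: float = 0.5
    seed: int = 0
    segment_lengths: tuple[float, float, float] = (0.41, 0.43, 0.20)
    step_width: float = 0.21
    step_width_sd: float = 0.06

    def validate(self) -> None:
        for name in ("n_participants", "n_trials_per_condition", "strides_per_trial"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.speed_sd < 0 or self.speed_trial_sd < 0 or self.step_width_sd < 0:
            raise ConfigurationError("speed and step-width SDs must be >= 0")
        if not self.conditions or len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("conditions must be non-empty and unique")
        for pair, by_cond in self.pause_fractions.items():
            for cond, frac in by_cond.items():
                if not 0.0 <= frac <= 1.0:
                    raise ConfigurationError(
                        f"pause_fractions[{pair!r}][{cond!r}] = {frac} outside [0, 1]"
                    )
        if any(l <= 0 for l in self.segment_lengths):
            raise ConfigurationError(f"segment lengths must be positive, got {self.segment_lengths}")
        for cond in self.conditions:
            if cond not in self.rom_means or cond not in self.rom_sds:
                raise ConfigurationError(f"rom_means/rom_sds missing condition {cond!r}")
            if cond not in self.condition_speed_means:
                raise ConfigurationError(f"condition_speed_means missing condition {cond!r}")


def null_config(**overrides) -> SyntheticConfig:
    """A cohort config with zero condition effects (all conditions identical).

    Participant-to-participant and trial-to-trial variability remain, so
    downstream condition comparisons test a true null.
    """
    base = SyntheticConfig(**overrides)
    na = base.conditions[0]
    cfg = replace(
        base,
        condition_speed_means={c: base.condition_speed_means[na] for c in base.conditions},
        rom_means={c: dict(base.rom_means[na]) for c in base.conditions},
        rom_sds={c: dict(base.rom_sds[na]) for c in base.conditions},
        pause_fractions={
            pair: {c: by_cond[na] for c in base.conditions}
            for pair, by_cond in base.pause_fractions.items()
        },
    )
    return cfg


@dataclass
class TrialTruth:
    """Generator-side ground truth for one trial (all frame indices 0-based)."""

    participant_id: str
    condition: str
    trial_index: int
    paretic_side: str
    speed: float
    cycle_frames: int
    foot_contacts: dict[str, list[int]]
    toe_offs: dict[str, list[int]]
    cycles: dict[str, list[list[int]]]
    pause_fractions_pairs: dict[str, float]
    pause_fractions_joints: dict[str, float]
    joint_maxima: dict[str, float]

    def validate(self) -> None:
        for side, fc in self.foot_contacts.items():
            if np.any(np.diff(fc) <= 0):
                raise ConfigurationError(f"{side}: truth contacts not strictly increasing")
        for d in (self.pause_fractions_pairs, self.pause_fractions_joints):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"truth pause fraction {k}={v} outside [0, 1]")


@dataclass
class GroundTruth:
    """Ground truth for a generated cohort, keyed by trial id."""

    trials: dict[str, TrialTruth] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {tid: asdict(tt) for tid, tt in self.trials.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(trials={tid: TrialTruth(**tt) for tid, tt in payload.items()})


def pair_to_joint_pauses(pair_fractions: dict[str, float]) -> dict[str, float]:
    """Convert pair-level one-joint-paused fractions to per-joint pause fractions.

    Solves p_hip + p_knee = D_hk, p_hip + p_ankle = D_ha, p_knee + p_ankle =
    D_ka (the additive model that holds when the three joints' pause windows
    are disjoint), clipping at 0 and at the per-joint cap that keeps the
    windows disjoint.
    """
    d_hk = pair_fractions["hip_knee"]
    d_ha = pair_fractions["hip_ankle"]
    d_ka = pair_fractions["knee_ankle"]
    p_hip = (d_hk + d_ha - d_ka) / 2.0
    p_knee = d_hk - p_hip
    p_ankle = d_ha - p_hip
    return {
        j: float(np.clip(p, 0.0, _MAX_JOINT_PAUSE))
        for j, p in (("hip", p_hip), ("knee", p_knee), ("ankle", p_ankle))
    }


def _stride_length(speed: float) -> float:
    # stride shortens with slower walking; 1.0 m at the cohort's 0.65 m/s mean
    return float(np.sqrt(max(speed, 1e-3) / 0.65))


def _refine_extremum(x: np.ndarray, nominal: int, half_window: int, mode: str) -> int:
    lo = max(0, nominal - half_window)
    hi = min(x.shape[0], nominal + half_window + 1)
    seg = x[lo:hi]
    return lo + int(np.argmax(seg) if mode == "max" else np.argmin(seg))


def _true_events(
    rec: TrialRecording, side: str, shift: int, n_cycle: int, n_contacts: int
) -> tuple[list[int], list[int]]:
    """Kinematic ground-truth events from the noise-free markers of one side."""
    heel_rel = rec.marker("heel", side)[:, 0] - rec.marker("sacrum")[:, 0]
    toe_rel = rec.marker("toe", side)[:, 0] - rec.marker("sacrum")[:, 0]
    half = max(2, int(round(0.2 * n_cycle)))
    contacts = [
        _refine_extremum(heel_rel, shift + j * n_cycle, half, "max") for j in range(n_contacts)
    ]
    toe_offs = [
        _refine_extremum(
            toe_rel, shift + int(round((j + NOMINAL_TOEOFF_PHASE) * n_cycle)), half, "min"
        )
        for j in range(n_contacts - 1)
    ]
    return contacts, toe_offs


def generate_cohort(config: SyntheticConfig | None = None) -> tuple[list[TrialRecording], GroundTruth]:
    """Generate the full synthetic cohort with ground-truth annotations.

    Deterministic for a fixed ``config.seed``; each participant consumes an
    independent child stream of the master seed, so cohorts are reproducible
    under participant reordering.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(cfg.n_participants)
    na = cfg.conditions[0]
    trials: list[TrialRecording] = []
    truth = GroundTruth()

    rom_clip = {"hip": (5.0, 60.0), "knee": (8.0, 80.0), "dorsiflexion": (0.5, 30.0), "plantarflexion": (1.0, 45.0)}

    for p_idx, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pid = f"P{p_idx + 1:02d}"
        paretic = "left" if rng.random() < 0.625 else "right"
        speed_base = float(np.clip(rng.normal(cfg.speed_mean, cfg.speed_sd), 0.24, 1.13))
        rom_base = {
            j: float(rng.normal(cfg.rom_means[na][j], cfg.rom_sds[na][j]))
            for j in ("hip", "knee", "dorsiflexion", "plantarflexion")
        }
        healthy = {
            "hip": cfg.healthy_maxima["hip"] + rng.normal(0, 1.5),
            "knee": cfg.healthy_maxima["knee"] + rng.normal(0, 2.0),
            "dorsiflexion": cfg.healthy_maxima["dorsiflexion"] + rng.normal(0, 1.0),
            "plantarflexion": cfg.healthy_maxima["plantarflexion"] + rng.normal(0, 1.5),
        }
        pause_base = {
            pair: float(np.clip(rng.normal(by_cond[na], cfg.pause_between_sd), 0.0, 0.45))
            for pair, by_cond in cfg.pause_fractions.items()
        }
        step_width = float(np.clip(rng.normal(cfg.step_width, cfg.step_width_sd), 0.08, 0.40))

        for cond in cfg.conditions:
            speed_cond = speed_base + (cfg.condition_speed_means[cond] - cfg.condition_speed_means[na])
            rom_cond = {
                j: rom_base[j] + (cfg.rom_means[cond][j] - cfg.rom_means[na][j])
                for j in rom_base
            }
            pause_pairs = {
                pair: float(np.clip(pause_base[pair] + (cfg.pause_fractions[pair][cond] - cfg.pause_fractions[pair][na]), 0.0, 0.45))
                for pair in pause_base
            }
            joint_pauses = pair_to_joint_pauses(pause_pairs)

            for t_idx in range(cfg.n_trials_per_condition):
                speed = float(np.clip(speed_cond + rng.normal(0, cfg.speed_trial_sd), 0.15, 1.4))
                maxima = {
                    j: float(np.clip(rom_cond[j] + rng.normal(0, cfg.rom_trial_sd), *rom_clip[j]))
                    for j in rom_cond
                }
                cycle_t = float(np.clip(_stride_length(speed) / speed, 0.6, 2.8))
                n_cycle = int(round(cycle_t * cfg.sample_rate))
                k = cfg.strides_per_trial

                paretic_cycle = generate_angle_cycle(
                    maxima, n_cycle / cfg.sample_rate, cfg.sample_rate, side=paretic
                )
                for joint, frac in joint_pauses.items():
                    if frac > 1e-9:
                        paretic_cycle = inject_pause(
                            paretic_cycle, joint, frac, _PAUSE_PLACEMENT[joint], side=paretic
                        )
                healthy_cycle = generate_angle_cycle(
                    healthy, n_cycle / cfg.sample_rate, cfg.sample_rate, side="right"
                ).angles["right"]

                n_total = (k + 1) * n_cycle
                shift_first = int(round(0.3 * n_cycle))
                shifts = {"right": shift_first, "left": shift_first + n_cycle // 2}
                angles = {}
                for s in ("left", "right"):
                    one = paretic_cycle.angles[paretic] if s == paretic else healthy_cycle
                    tiled = np.tile(one, (k + 1, 1))
                    angles[s] = np.roll(tiled, shifts[s], axis=0)
                series = JointAngleSeries(sample_rate=cfg.sample_rate, angles=angles)

                rec = angles_to_markers(
                    series,
                    segment_lengths=cfg.segment_lengths,
                    pelvis_speed=speed,
                    step_width=step_width,
                    participant_id=pid,
                    condition=cond,
                    paretic_side=paretic,
                )

                contacts, toe_offs, cycles = {}, {}, {}
                for s in ("left", "right"):
                    n_contacts = k + 1
                    fc, to = _true_events(rec, s, shifts[s], n_cycle, n_contacts)
                    contacts[s], toe_offs[s] = fc, to
                    cycles[s] = [[fc[i], fc[i + 1]] for i in range(len(fc) - 1)]

                if cfg.noise_sd_marker > 0:
                    for name in rec.markers:
                        rec.markers[name] = rec.markers[name] + rng.normal(
                            0.0, cfg.noise_sd_marker, rec.markers[name].shape
                        )

                trial_id = f"{pid}_{cond}_t{t_idx + 1}"
                tt = TrialTruth(
                    participant_id=pid,
                    condition=cond,
                    trial_index=t_idx + 1,
                    paretic_side=paretic,
                    speed=speed,
                    cycle_frames=n_cycle,
                    foot_contacts=contacts,
                    toe_offs=toe_offs,
                    cycles=cycles,
                    pause_fractions_pairs=pause_pairs,
                    pause_fractions_joints=joint_pauses,
                    joint_maxima=maxima,
                )
                tt.validate()
                truth.trials[trial_id] = tt
                trials.append(rec)

    return trials, truth


def generate_comfort_scores(
    n_participants: int = 16,
    seed: int | np.random.Generator = 0,
    means: tuple[float, float, float] = (4.3, 4.5, 4.4),
    sds: tuple[float, float, float] = (2.9, 2.3, 2.3),
):
    """Per-participant comfort ratings (0-10 visual analog scale, 0 = very
    comfortable) for the three assisted conditions; paired via a participant
    random effect."""
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conds = ("afo", "newgait_dorsiflexion", "newgait_full")
    u = rng.normal(0.0, 1.5, n_participants)
    data = {}
    for cond, mu, sd in zip(conds, means, sds):
        resid_sd = float(np.sqrt(max(sd**2 - 1.5**2, 0.3)))
        data[cond] = np.clip(mu + u + rng.normal(0.0, resid_sd, n_participants), 0.0, 10.0)
    return pd.DataFrame(data, index=[f"P{i + 1:02d}" for i in range(n_participants)])
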
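"""Shared domain types: trial recordings, joint-angle series, gait-cycle sets.

Coordinate conventions (lab frame): X = direction of progression, Y =
mediolateral (left positive), Z = vertical up, positions in meters. Sagittal
angle conventions, in degrees: hip flexion positive, knee flexion positive,
ankle dorsiflexion positive / plantarflexion negative.

Frames are 0-based; gait cycles are half-open frame intervals
``[start, stop)`` between two consecutive same-side foot contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataQualityError

#: Walking conditions in the order they are reported.
CONDITIONS = ("no_assistance", "afo", "newgait_dorsiflexion", "newgait_full")

SIDES = ("left", "right")
SIDE_SUFFIX = {"left": "L", "right": "R"}

JOINTS = ("hip", "knee", "ankle")

#: Per-side markers every recording must provide (plus the shared sacrum).
REQUIRED_SIDE_MARKERS = ("hip", "knee", "ankle", "heel", "toe")

#: The 12 metrics of the cohort table: 5 spatiotemporal + 4 kinematic maxima
#: + 3 decomposition indices.
METRICS = (
    "gait_velocity",
    "step_length",
    "step_width",
    "double_support",
    "foot_clearance",
    "max_hip_flexion",
    "max_knee_flexion",
    "max_ankle_plantarflexion",
    "max_ankle_dorsiflexion",
    "hip_knee_decomposition",
    "hip_ankle_decomposition",
    "knee_ankle_decomposition",
)

JOINT_PAIRS = (("hip", "knee"), ("hip", "ankle"), ("knee", "ankle"))


def marker_name(base: str, side: str | None = None) -> str:
    """Column/marker name for a base marker and optional side."""
    if side is None:
        return base
    return f"{base}_{SIDE_SUFFIX[side]}"


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"


@dataclass
class TrialRecording:
    """One walking trial: marker trajectories at a fixed sample rate.

    ``markers`` maps marker names (``sacrum``, ``hip_L`` ... ``toe_R``) to
    ``(n, 3)`` float arrays in meters, lab frame as documented in this module.
    """

    participant_id: str
    condition: str
    sample_rate: float
    markers: dict[str, np.ndarray]
    paretic_side: str = "left"

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sample_rate

    def marker(self, base: str, side: str | None = None) -> np.ndarray:
        return self.markers[marker_name(base, side)]

    def required_names(self) -> list[str]:
        names = ["sacrum"]
        for side in SIDES:
            names += [marker_name(m, side) for m in REQUIRED_SIDE_MARKERS]
        return names

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.paretic_side not in SIDES:
            raise ConfigurationError(f"paretic_side must be one of {SIDES}, got {self.paretic_side!r}")
        missing = [m for m in self.required_names() if m not in self.markers]
        if missing:
            raise DataQualityError(f"required marker absent: {', '.join(missing)}")
        lengths = {name: arr.shape[0] for name, arr in self.markers.items()}
        if len(set(lengths.values())) != 1:
            raise DataQualityError(f"marker series lengths differ: {lengths}")
        n = self.n_frames
        if n < 2:
            raise DataQualityError(f"recording too short: {n} frame(s)")
        for name, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise DataQualityError(f"marker {name!r} is not an (n, 3) array")
            if np.isnan(arr).any():
                raise DataQualityError(f"marker {name!r} contains NaN after gap-fill")
            if np.min(arr[:, 2]) < -0.01:
                raise DataQualityError(
                    f"marker {name!r} drops below the floor (min Z = {np.min(arr[:, 2]):.3f} m)"
                )


@dataclass
class JointAngleSeries:
    """Sagittal hip/knee/ankle angles per leg, degrees, at ``sample_rate``.

    ``angles`` maps side -> ``(n, 3)`` array with columns ordered as
    :data:`JOINTS` (hip, knee, ankle).
    """

    sample_rate: float
    angles: dict[str, np.ndarray]

    @property
    def sides(self) -> tuple[str, ...]:
        return tuple(self.angles)

    @property
    def n_samples(self) -> int:
        return next(iter(self.angles.values())).shape[0]

    def joint(self, joint: str, side: str | None = None) -> np.ndarray:
        """1-D angle trace for one joint; side may be omitted for single-leg series."""
        if side is None:
            if len(self.angles) != 1:
                raise ConfigurationError("side must be given for a two-legged series")
            side = next(iter(self.angles))
        if joint not in JOINTS:
            raise ConfigurationError(f"unknown joint {joint!r}; expected one of {JOINTS}")
        return self.angles[side][:, JOINTS.index(joint)]

    def copy(self) -> "JointAngleSeries":
        return JointAngleSeries(
            sample_rate=self.sample_rate,
            angles={s: a.copy() for s, a in self.angles.items()},
        )

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError(f"sample_rate must be positive, got {self.sample_rate}")
        for side, arr in self.angles.items():
            if arr.ndim != 2 or arr.shape[1] != len(JOINTS):
                raise ConfigurationError(f"angles[{side!r}] is not an (n, 3) array")
            if np.max(np.abs(arr)) > 180.0:
                raise DataQualityError(f"angles[{side!r}] exceed |180| degrees")


@dataclass
class SideEvents:
    """Detected events for one side, frame indices, strictly increasing."""

    foot_contacts: np.ndarray
    toe_offs: np.ndarray

    @property
    def cycles(self) -> list[tuple[int, int]]:
        fc = self.foot_contacts
        return [(int(fc[i]), int(fc[i + 1])) for i in range(len(fc) - 1)]


# Physiologic gait-cycle duration band; cycles outside it are flagged, not dropped.
CYCLE_DURATION_BOUNDS_S = (0.4, 3.0)


@dataclass
class GaitCycleSet:
    """Foot-contact / toe-off events and the derived cycles for both sides."""

    sample_rate: float
    sides: dict[str, SideEvents] = field(default_factory=dict)

    def cycles(self, side: str) -> list[tuple[int, int]]:
        return self.sides[side].cycles

    def flagged(self, side: str) -> list[bool]:
        """True for cycles whose duration is outside the physiologic band."""
        lo, hi = CYCLE_DURATION_BOUNDS_S
        out = []
        for start, stop in self.sides[side].cycles:
            dur = (stop - start) / self.sample_rate
            out.append(not (lo <= dur <= hi))
        return out

    def validate(self) -> None:
        for side, ev in self.sides.items():
            fc, to = np.asarray(ev.foot_contacts), np.asarray(ev.toe_offs)
            if np.any(np.diff(fc) <= 0) or np.any(np.diff(to) <= 0):
                raise DataQualityError(f"{side}: event frames not strictly increasing")
            for a, b in ev.cycles:
                inside = np.sum((to > a) & (to < b))
                if inside != 1:
                    raise DataQualityError(
                        f"{side}: cycle [{a}, {b}) contains {inside} toe-offs (expected 1)"
                    )
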
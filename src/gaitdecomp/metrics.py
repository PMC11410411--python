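"""Spatiotemporal gait characteristics and sagittal kinematics from markers.

Joint angles come from a planar segment model in the plane spanned by the
direction of progression and the vertical: the hip angle is the forward tilt
of the thigh (hip->knee) from vertical, knee flexion the angle between thigh
and shank, and the ankle angle the foot (heel->toe) pitch relative to the
shank's perpendicular, dorsiflexion positive. This deliberately ignores
frontal/transverse rotations, which the analysis does not use.

Five spatiotemporal characteristics are computed per gait cycle:

* gait velocity — sacrum horizontal path length divided by cycle duration;
* step length — anterior heel-to-heel distance at each foot contact in the
  cycle (both sides' steps averaged);
* step width — mediolateral heel-to-heel distance at those contacts;
* double support — percentage of the cycle with both feet in stance,
  derived from both sides' contact and toe-off events;
* foot clearance — peak toe height during swing above the mean toe height
  of flat-foot stance frames (|foot pitch| < 10 deg).

Kinematic maxima are per-cycle extrema of the sagittal angles; ankle
plantarflexion is reported as a positive magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._filters import lowpass
from .core import (
    GaitCycleSet,
    JointAngleSeries,
    TrialRecording,
    other_side,
    SIDES,
)
from .events import progression_axis
from .exceptions import DataQualityError, DomainError

__all__ = [
    "SpatiotemporalSummary",
    "KinematicMaxima",
    "compute_sagittal_angles",
    "spatiotemporal",
    "kinematic_maxima",
]

#: Stance frames with |foot pitch| below this count as foot-flat (degrees).
FOOT_FLAT_PITCH_DEG = 10.0


def _segment_angle_from_vertical(vec_x: np.ndarray, vec_z: np.ndarray, name: str) -> np.ndarray:
    norm = np.hypot(vec_x, vec_z)
    if np.any(norm < 1e-9):
        frames = np.where(norm < 1e-9)[0]
        raise DataQualityError(f"degenerate (zero-length) {name} segment at frame(s) {frames[:5]}")
    return np.degrees(np.arctan2(vec_x, -vec_z))


def compute_sagittal_angles(recording: TrialRecording) -> JointAngleSeries:
    """Sagittal hip/knee/ankle angle series for both legs, in degrees."""
    recording.validate()
    axis = progression_axis(recording)

    def proj(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return arr[:, :2] @ axis, arr[:, 2]

    angles = {}
    for side in SIDES:
        hip_m, knee_m = recording.marker("hip", side), recording.marker("knee", side)
        ankle_m = recording.marker("ankle", side)
        heel_m, toe_m = recording.marker("heel", side), recording.marker("toe", side)

        tx, tz = proj(knee_m - hip_m)
        theta_thigh = _segment_angle_from_vertical(tx, tz, f"thigh ({side})")
        sx, sz = proj(ankle_m - knee_m)
        theta_shank = _segment_angle_from_vertical(sx, sz, f"shank ({side})")
        fx, fz = proj(toe_m - heel_m)
        fnorm = np.hypot(fx, fz)
        if np.any(fnorm < 1e-9):
            raise DataQualityError(f"degenerate (zero-length) foot segment ({side})")
        pitch = np.degrees(np.arctan2(fz, fx))

        hip = theta_thigh
        knee = theta_thigh - theta_shank
        ankle = pitch - theta_shank
        angles[side] = np.column_stack([hip, knee, ankle])

    series = JointAngleSeries(sample_rate=recording.sample_rate, angles=angles)
    series.validate()
    return series


def _stance_mask(n: int, contacts: np.ndarray, toe_offs: np.ndarray) -> np.ndarray:
    """Per-frame stance state from alternating contact/toe-off events."""
    events = sorted(
        [(int(f), True) for f in contacts] + [(int(f), False) for f in toe_offs]
    )
    mask = np.empty(n, dtype=bool)
    # before the first event: in stance iff the first event is a toe-off
    state = not events[0][1] if events else True
    prev = 0
    for frame, is_contact in events:
        mask[prev:frame] = state
        state = is_contact
        prev = frame
    mask[prev:] = state
    return mask


@dataclass
class SpatiotemporalSummary:
    """Per-cycle spatiotemporal values and their stride averages."""

    per_cycle: dict[str, list[float]] = field(default_factory=dict)

    @property
    def means(self) -> dict[str, float]:
        out = {}
        for metric, vals in self.per_cycle.items():
            arr = np.asarray(vals, dtype=float)
            ok = ~np.isnan(arr)
            out[metric] = float(np.mean(arr[ok])) if ok.any() else float("nan")
        return out


def spatiotemporal(
    recording: TrialRecording,
    events: GaitCycleSet,
    side: str | None = None,
    filter_cutoff: float = 6.0,
) -> SpatiotemporalSummary:
    """The five spatiotemporal characteristics per cycle of ``side``.

    ``side`` defaults to the recording's paretic side. Double support needs
    the contralateral events; if they are missing it is reported as NaN while
    the other metrics are still computed.
    """
    side = side or recording.paretic_side
    if side not in events.sides or len(events.sides[side].foot_contacts) < 2:
        raise DomainError(f"no complete cycle on side {side!r}")
    axis = progression_axis(recording)
    perp = np.array([-axis[1], axis[0]])
    rate = recording.sample_rate
    n = recording.n_frames

    sacrum_xy = lowpass(recording.marker("sacrum")[:, :2], rate, filter_cutoff)
    heel = {s: recording.marker("heel", s) for s in SIDES}
    toe_z = lowpass(recording.marker("toe", side)[:, 2], rate, filter_cutoff)
    foot_vec = recording.marker("toe", side) - recording.marker("heel", side)
    pitch = np.degrees(
        np.arctan2(lowpass(foot_vec[:, 2], rate, filter_cutoff), foot_vec[:, :2] @ axis)
    )

    contra = other_side(side)
    have_contra = contra in events.sides and len(events.sides[contra].foot_contacts) > 0
    stance = {
        s: _stance_mask(n, events.sides[s].foot_contacts, events.sides[s].toe_offs)
        for s in events.sides
    }
    all_contacts = sorted(
        (int(f), s) for s in events.sides for f in events.sides[s].foot_contacts
    )

    own = events.sides[side]
    summary = SpatiotemporalSummary(
        per_cycle={m: [] for m in ("gait_velocity", "step_length", "step_width", "double_support", "foot_clearance")}
    )
    for a, b in own.cycles:
        dur = (b - a) / rate
        seg = sacrum_xy[a : b + 1] if b < n else sacrum_xy[a:b]
        path = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
        summary.per_cycle["gait_velocity"].append(path / dur)

        lengths, widths = [], []
        for frame, s in all_contacts:
            if a <= frame < b:
                diff = heel[s][frame, :2] - heel[other_side(s)][frame, :2]
                lengths.append(abs(float(diff @ axis)))
                widths.append(abs(float(diff @ perp)))
        summary.per_cycle["step_length"].append(float(np.mean(lengths)) if lengths else float("nan"))
        summary.per_cycle["step_width"].append(float(np.mean(widths)) if widths else float("nan"))

        if have_contra:
            both = stance[side][a:b] & stance[contra][a:b]
            summary.per_cycle["double_support"].append(100.0 * float(np.mean(both)))
        else:
            summary.per_cycle["double_support"].append(float("nan"))

        to_in = own.toe_offs[(own.toe_offs > a) & (own.toe_offs < b)]
        to_frame = int(to_in[0]) if len(to_in) else a + (b - a) // 2
        stance_pitch = pitch[a:to_frame]
        stance_toe = toe_z[a:to_frame]
        flat = np.abs(stance_pitch) < FOOT_FLAT_PITCH_DEG
        if flat.any():
            baseline = float(np.mean(stance_toe[flat]))
        else:
            q = np.quantile(stance_toe, 0.25) if len(stance_toe) else np.nan
            baseline = float(np.mean(stance_toe[stance_toe <= q])) if len(stance_toe) else float("nan")
        swing_peak = float(np.max(toe_z[to_frame:b])) if to_frame < b else float("nan")
        clearance = swing_peak - baseline
        summary.per_cycle["foot_clearance"].append(max(clearance, 0.0))

    return summary


@dataclass
class KinematicMaxima:
    """Per-cycle sagittal extrema (degrees; plantarflexion as magnitude)."""

    max_hip_flexion: float
    max_knee_flexion: float
    max_ankle_dorsiflexion: float
    max_ankle_plantarflexion: float

    def as_dict(self) -> dict[str, float]:
        return {
            "max_hip_flexion": self.max_hip_flexion,
            "max_knee_flexion": self.max_knee_flexion,
            "max_ankle_dorsiflexion": self.max_ankle_dorsiflexion,
            "max_ankle_plantarflexion": self.max_ankle_plantarflexion,
        }


def kinematic_maxima(
    angles: JointAngleSeries, cycle: tuple[int, int], side: str | None = None
) -> KinematicMaxima:
    """Extrema of the sagittal angles within one half-open cycle interval."""
    a, b = cycle
    if not (0 <= a < b <= angles.n_samples):
        raise DomainError(f"cycle [{a}, {b}) outside series of length {angles.n_samples}")
    if side is None:
        if len(angles.angles) != 1:
            raise DomainError("side must be given for a two-legged series")
        side = angles.sides[0]
    arr = angles.angles[side][a:b]
    ankle = arr[:, 2]
    ankle_min = float(np.min(ankle))
    return KinematicMaxima(
        max_hip_flexion=float(np.max(arr[:, 0])),
        max_knee_flexion=float(np.max(arr[:, 1])),
        max_ankle_dorsiflexion=float(np.max(ankle)),
        max_ankle_plantarflexion=abs(ankle_min) if ankle_min < 0 else 0.0,
    )
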
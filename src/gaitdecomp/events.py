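"""Coordinate-based gait-event detection and cycle segmentation.

Foot contacts and toe-offs are found from marker kinematics alone (no force
plates): a foot contact is a local maximum of the heel marker's position
along the direction of progression *relative to the sacrum*, and a toe-off
is a local minimum of the toe marker's relative position — the standard
coordinate-based method for treadmill and overground data. Working in
sacrum-relative coordinates makes detection invariant to where the walkway
is and to uniform forward motion.

The direction of progression is estimated as the principal horizontal
direction of sacrum displacement, so imported trials need not be aligned
with the lab X axis. Signals are low-pass filtered (zero-phase, 6 Hz) before
peak picking; peaks are required to be at least 0.4 s apart. Partial strides
before the first and after the last contact are excluded. A gait cycle is
the half-open frame interval between consecutive same-side contacts.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from ._filters import lowpass
from .core import GaitCycleSet, SideEvents, SIDES, TrialRecording
from .exceptions import TrialTooShortError

__all__ = ["progression_axis", "detect_events", "segment_cycles", "events_table"]

#: Minimum separation between same-type events (seconds).
MIN_EVENT_SEPARATION_S = 0.4


def progression_axis(recording: TrialRecording) -> np.ndarray:
    """Unit vector of the principal horizontal direction of sacrum travel."""
    xy = recording.marker("sacrum")[:, :2]
    disp = xy - xy.mean(axis=0)
    # principal direction of horizontal displacement, oriented along net travel
    _, _, vt = np.linalg.svd(disp, full_matrices=False)
    axis = vt[0]
    net = xy[-1] - xy[0]
    if np.dot(axis, net) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _relative_progression(recording: TrialRecording, base: str, side: str, axis: np.ndarray) -> np.ndarray:
    marker = recording.marker(base, side)[:, :2]
    sacrum = recording.marker("sacrum")[:, :2]
    return (marker - sacrum) @ axis


def detect_events(recording: TrialRecording, filter_cutoff: float = 6.0) -> GaitCycleSet:
    """Detect foot contacts and toe-offs for both sides.

    Raises :class:`TrialTooShortError` when the recording does not span two
    same-side foot contacts on each side.
    """
    recording.validate()
    axis = progression_axis(recording)
    rate = recording.sample_rate
    min_dist = max(1, int(round(MIN_EVENT_SEPARATION_S * rate)))
    out = GaitCycleSet(sample_rate=rate)
    for side in SIDES:
        heel_rel = lowpass(_relative_progression(recording, "heel", side, axis), rate, filter_cutoff)
        toe_rel = lowpass(_relative_progression(recording, "toe", side, axis), rate, filter_cutoff)
        # require a minimal oscillation; a static stance has no gait events
        prominence = 0.01 * max(np.ptp(heel_rel), 1e-9)
        contacts, _ = sp_signal.find_peaks(heel_rel, distance=min_dist, prominence=max(prominence, 0.005))
        toe_offs, _ = sp_signal.find_peaks(-toe_rel, distance=min_dist, prominence=max(prominence, 0.005))
        if len(contacts) < 2:
            raise TrialTooShortError(
                f"{side}: {len(contacts)} foot contact(s) detected; need at least 2 for one cycle"
            )
        # keep exactly one toe-off per cycle: the deepest toe-back minimum inside it
        kept: list[int] = []
        for a, b in zip(contacts[:-1], contacts[1:]):
            inside = toe_offs[(toe_offs > a) & (toe_offs < b)]
            if len(inside) == 0:
                seg = np.asarray(toe_rel[a + 1 : b])
                kept.append(a + 1 + int(np.argmin(seg)))
            else:
                kept.append(int(inside[np.argmin(toe_rel[inside])]))
        out.sides[side] = SideEvents(
            foot_contacts=np.asarray(contacts, dtype=int),
            toe_offs=np.asarray(kept, dtype=int),
        )
    out.validate()
    return out


def segment_cycles(events: GaitCycleSet, side: str) -> list[tuple[int, int]]:
    """Half-open cycle intervals [FC_i, FC_{i+1}) for one side.

    k contacts yield k-1 cycles; partial data outside the first/last contact
    is excluded.
    """
    if side not in events.sides or len(events.sides[side].foot_contacts) < 2:
        raise TrialTooShortError(f"{side}: need at least 2 foot contacts to segment cycles")
    return events.cycles(side)


def events_table(events: GaitCycleSet):
    """Events as a tidy DataFrame (side, event, frame, time_s)."""
    import pandas as pd

    rows = []
    for side, ev in events.sides.items():
        for f in ev.foot_contacts:
            rows.append((side, "foot_contact", int(f), f / events.sample_rate))
        for f in ev.toe_offs:
            rows.append((side, "toe_off", int(f), f / events.sample_rate))
    df = pd.DataFrame(rows, columns=["side", "event", "frame", "time_s"])
    return df.sort_values(["side", "frame"], ignore_index=True)
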
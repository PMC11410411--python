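"""Sagittal inverse kinematics and spatiotemporal characteristics."""

import numpy as np
import pytest

import gaitdecomp as gd
from gaitdecomp.core import GaitCycleSet, SideEvents
from conftest import HEALTHY_MAXIMA


def _standing_markers(n=200, foot_pitch_deg=0.0, speed=0.5):
    """Both legs vertical; foot flat unless pitched toes-up by foot_pitch_deg."""
    t = np.arange(n) / 100.0
    x = speed * t
    psi = np.radians(foot_pitch_deg)
    markers = {"sacrum": np.column_stack([x, np.zeros(n), np.full(n, 0.9)])}
    for side, y in (("L", 0.1), ("R", -0.1)):
        hip = np.column_stack([x, np.full(n, y), np.full(n, 0.9)])
        knee = hip + [0, 0, -0.4]
        ankle = knee + [0, 0, -0.43]
        heel = ankle + [-0.05 * np.cos(psi), 0, -0.05 * np.sin(psi)]
        toe = ankle + [0.15 * np.cos(psi), 0, 0.15 * np.sin(psi)]
        for base, arr in (("hip", hip), ("knee", knee), ("ankle", ankle), ("heel", heel), ("toe", toe)):
            markers[f"{base}_{side}"] = arr + [0, 0, 0.06]
    return gd.TrialRecording("stand", "no_assistance", 100.0, markers, "left")


def test_neutral_pose_gives_zero_angles():
    ang = gd.compute_sagittal_angles(_standing_markers())
    for side in ("left", "right"):
        assert np.max(np.abs(ang.angles[side])) < 1e-9


def test_foot_pitched_toes_up_reads_as_dorsiflexion():
    ang = gd.compute_sagittal_angles(_standing_markers(foot_pitch_deg=15.0))
    assert np.allclose(ang.angles["left"][:, 2], 15.0, atol=1e-9)
    assert np.max(np.abs(ang.angles["left"][:, :2])) < 1e-9


def test_angles_recovered_from_synthetic_markers(healthy_trial):
    rec, tiled = healthy_trial
    ang = gd.compute_sagittal_angles(rec)
    expected = np.roll(tiled, 36, axis=0)
    assert np.max(np.abs(ang.angles["right"] - expected)) < 0.5


def test_velocity_recovered_within_one_percent(clean_cohort):
    _, trials, truth = clean_cohort
    for rec, (tid, tt) in zip(trials, truth.trials.items()):
        ev = gd.detect_events(rec)
        st = gd.spatiotemporal(rec, ev, side=rec.paretic_side)
        est = float(np.mean(st.per_cycle["gait_velocity"]))
        assert abs(est - tt.speed) / tt.speed < 0.01


def test_velocity_times_duration_matches_sacrum_stride(clean_cohort):
    _, trials, _ = clean_cohort
    rec = trials[0]
    ev = gd.detect_events(rec)
    side = rec.paretic_side
    st = gd.spatiotemporal(rec, ev, side=side)
    sac = rec.marker("sacrum")[:, 0]
    for (a, b), v in zip(ev.cycles(side), st.per_cycle["gait_velocity"]):
        stride = sac[b] - sac[a]
        assert abs(v * (b - a) / rec.sample_rate - stride) / stride < 0.02


def test_double_support_is_100_when_no_swing():
    rec = _standing_markers(n=200)
    ev = GaitCycleSet(
        sample_rate=100.0,
        sides={
            "left": SideEvents(np.array([0, 100]), np.array([], dtype=int)),
            "right": SideEvents(np.array([0]), np.array([], dtype=int)),
        },
    )
    st = gd.spatiotemporal(rec, ev, side="left")
    assert st.per_cycle["double_support"][0] == pytest.approx(100.0)


def _clearance_trial(lift=0.18):
    """Flat-foot stance for half the cycle, toe raised by ``lift`` in swing."""
    n = 240
    rec = _standing_markers(n=n, speed=0.8)
    z = np.zeros(n)
    for c in (0, 120):
        sw = np.arange(c + 60, min(c + 120, n))
        z[sw] = lift * np.sin(np.pi * (sw - (c + 60)) / 60.0)
    for base in ("heel", "toe"):
        rec.markers[f"{base}_L"] = rec.markers[f"{base}_L"] + np.column_stack([np.zeros(n)] * 2 + [z])
    ev = GaitCycleSet(
        sample_rate=100.0,
        sides={
            "left": SideEvents(np.array([0, 120, 239]), np.array([60, 180])),
            "right": SideEvents(np.array([60, 180]), np.array([120])),
        },
    )
    return rec, ev


def test_foot_clearance_recovers_injected_toe_lift():
    rec, ev = _clearance_trial(lift=0.18)
    st = gd.spatiotemporal(rec, ev, side="left")
    assert st.per_cycle["foot_clearance"][0] == pytest.approx(0.18, abs=0.005)


def test_foot_clearance_is_linear_in_lift():
    c1 = gd.spatiotemporal(*_clearance_trial(0.12), side="left").per_cycle["foot_clearance"][0]
    c2 = gd.spatiotemporal(*_clearance_trial(0.24), side="left").per_cycle["foot_clearance"][0]
    assert c2 == pytest.approx(2 * c1, rel=0.05)
    assert c1 >= 0


def test_metrics_invariant_to_lab_frame_rotation(clean_cohort):
    _, trials, _ = clean_cohort
    rec = trials[0]
    ev = gd.detect_events(rec)
    base = gd.spatiotemporal(rec, ev, side=rec.paretic_side).means
    ang = np.radians(120.0)
    rot = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
    moved = gd.TrialRecording(
        rec.participant_id, rec.condition, rec.sample_rate,
        {m: arr @ rot.T + np.array([-2.0, 4.0, 0.0]) for m, arr in rec.markers.items()},
        rec.paretic_side,
    )
    got = gd.spatiotemporal(moved, gd.detect_events(moved), side=rec.paretic_side).means
    for metric, val in base.items():
        assert got[metric] == pytest.approx(val, rel=1e-6, abs=1e-9)


def test_kinematic_maxima_trivial_and_template():
    zero = gd.JointAngleSeries(100.0, {"right": np.zeros((50, 3))})
    km = gd.kinematic_maxima(zero, (0, 50))
    assert km.as_dict() == {
        "max_hip_flexion": 0.0,
        "max_knee_flexion": 0.0,
        "max_ankle_dorsiflexion": 0.0,
        "max_ankle_plantarflexion": 0.0,
    }
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0)
    km = gd.kinematic_maxima(cyc, (0, 120))
    assert km.max_hip_flexion == pytest.approx(30.0, abs=0.1)
    assert km.max_knee_flexion == pytest.approx(60.0, abs=0.1)
    assert km.max_ankle_dorsiflexion == pytest.approx(15.0, abs=0.1)
    assert km.max_ankle_plantarflexion == pytest.approx(20.0, abs=0.1)


def test_kinematic_maxima_table_row_ankle_values():
    cyc = gd.generate_angle_cycle(
        {"hip": 26.8, "knee": 35.7, "dorsiflexion": 9.6, "plantarflexion": 24.6}, 1.2, 100.0
    )
    km = gd.kinematic_maxima(cyc, (0, 120))
    assert km.max_ankle_dorsiflexion == pytest.approx(9.6, abs=0.1)
    assert km.max_ankle_plantarflexion == pytest.approx(24.6, abs=0.1)


def test_noise_free_cohort_mean_dorsiflexion_matches_population():
    cfg = gd.SyntheticConfig(
        n_participants=16, n_trials_per_condition=1, noise_sd_marker=0.0, seed=2
    )
    trials, truth = gd.generate_cohort(cfg)
    vals = []
    for rec, (tid, tt) in zip(trials, truth.trials.items()):
        if rec.condition != "no_assistance":
            continue
        ev = gd.detect_events(rec)
        ang = gd.compute_sagittal_angles(rec)
        per = [
            gd.kinematic_maxima(ang, c, side=rec.paretic_side).max_ankle_dorsiflexion
            for c in ev.cycles(rec.paretic_side)
        ]
        vals.append(np.mean(per))
    sem = 4.21 / np.sqrt(16)
    assert abs(np.mean(vals) - 9.6) <= 2 * sem
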
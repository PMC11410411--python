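"""Generator: angle templates, pause injection, forward kinematics, cohorts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gaitdecomp as gd
from gaitdecomp.decomposition import angular_velocity, decomposition_index, pause_mask
from gaitdecomp.exceptions import ConfigurationError, DomainError
from gaitdecomp.synthetic import pair_to_joint_pauses

from conftest import HEALTHY_MAXIMA


@pytest.mark.parametrize(
    "maxima",
    [
        HEALTHY_MAXIMA,
        {"hip": 26.8, "knee": 35.7, "dorsiflexion": 9.6, "plantarflexion": 24.6},
        {"hip": 0.0, "knee": 0.0, "dorsiflexion": 0.0, "plantarflexion": 0.0},
    ],
)
def test_angle_cycle_extrema_match_requested(maxima):
    cyc = gd.generate_angle_cycle(maxima, 1.2, 100.0)
    arr = cyc.angles["right"]
    assert arr.shape == (120, 3)
    assert abs(arr[:, 0].max() - maxima["hip"]) < 0.1
    assert abs(arr[:, 1].max() - maxima["knee"]) < 0.1
    assert abs(arr[:, 2].max() - maxima["dorsiflexion"]) < 0.1
    assert abs(-arr[:, 2].min() - maxima["plantarflexion"]) < 0.1 or maxima["plantarflexion"] == 0


def test_zero_maxima_give_constant_zero_series():
    cyc = gd.generate_angle_cycle({k: 0.0 for k in HEALTHY_MAXIMA}, 1.2, 100.0)
    assert np.allclose(cyc.angles["right"], 0.0)


def test_angle_cycle_is_periodic():
    from gaitdecomp.synthetic import _ankle_shape, _hip_shape, _knee_shape

    # the waveforms close exactly: value at phase 1 equals value at phase 0
    ends = np.array([0.0, 1.0])
    for shape in (_hip_shape, _knee_shape, _ankle_shape):
        assert abs(shape(ends)[0] - shape(ends)[1]) < 1e-9
    # tiled copies join without a kink: the seam step is no larger than the
    # largest step inside the cycle
    one = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0).angles["right"]
    seam = np.abs(one[0] - one[-1])
    internal = np.max(np.abs(np.diff(one, axis=0)), axis=0)
    assert np.all(seam <= 1.5 * internal)


@pytest.mark.parametrize("dur,rate", [(-1.0, 100.0), (1.2, 0.0), (0.0, 100.0)])
def test_angle_cycle_rejects_nonpositive_duration_or_rate(dur, rate):
    with pytest.raises(ConfigurationError):
        gd.generate_angle_cycle(HEALTHY_MAXIMA, dur, rate)


@given(
    hip=st.floats(0, 60),
    knee=st.floats(0, 80),
    dorsi=st.floats(0, 30),
    plantar=st.floats(0, 45),
    dur=st.floats(0.8, 2.5),
)
def test_angle_cycle_extrema_property(hip, knee, dorsi, plantar, dur):
    maxima = {"hip": hip, "knee": knee, "dorsiflexion": dorsi, "plantarflexion": plantar}
    arr = gd.generate_angle_cycle(maxima, dur, 100.0).angles["right"]
    assert abs(arr[:, 0].max() - hip) < 0.1
    assert abs(arr[:, 1].max() - knee) < 0.1
    assert abs(arr[:, 2].max() - dorsi) < 0.1
    if dorsi + plantar > 0:
        assert abs(-arr[:, 2].min() - plantar) < 0.1


def test_inject_pause_identity_and_full_freeze():
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0)
    same = gd.inject_pause(cyc, "knee", 0.0)
    assert np.array_equal(same.angles["right"], cyc.angles["right"])
    frozen = gd.inject_pause(cyc, "knee", 1.0, placement=0.25)
    knee = frozen.angles["right"][:, 1]
    assert np.ptp(knee) == 0.0
    # other joints untouched
    assert np.array_equal(frozen.angles["right"][:, 0], cyc.angles["right"][:, 0])


@given(frac=st.floats(0.05, 0.9), placement=st.floats(0, 1))
def test_inject_pause_window_has_zero_velocity(frac, placement):
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0)
    out = gd.inject_pause(cyc, "hip", frac, placement)
    n = 120
    m = round(frac * n)
    i0 = min(round(placement * n), n - m)
    window = out.angles["right"][i0 : i0 + m, 0]
    assert np.ptp(window) == 0.0
    assert out.n_samples == n
    # endpoint continuity: first sample unchanged
    assert abs(out.angles["right"][0, 0] - cyc.angles["right"][0, 0]) < 1e-9


def test_inject_pause_rejects_bad_fraction():
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0)
    with pytest.raises(DomainError):
        gd.inject_pause(cyc, "knee", 1.5)


def test_injected_pause_matches_direct_velocity_threshold_oracle():
    """Decomposition of an injected series equals brute-force enumeration of
    directly thresholded velocities."""
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0)
    out = gd.inject_pause(cyc, "knee", 0.2, placement=0.55)
    vel = angular_velocity(out.angles["right"], 100.0, None)
    # oracle: per-frame enumeration with the same 5% relative threshold
    paused = []
    for j in range(2):
        v = vel[:, j]
        thr = 0.05 * np.max(np.abs(v))
        paused.append(np.abs(v) < thr)
    one = sum(1 for a, b in zip(*paused) if a != b)
    moving = sum(1 for a, b in zip(*paused) if not (a and b))
    oracle = 100.0 * one / moving
    m_hip = pause_mask(vel[:, 0], None, 0.05, 1.0)
    m_knee = pause_mask(vel[:, 1], None, 0.05, 1.0)
    assert decomposition_index(m_hip, m_knee) == pytest.approx(oracle, abs=1e-12)
    # the pause window itself is ~20% of the cycle at exactly zero velocity
    exact_zero = np.sum(np.abs(np.diff(out.angles["right"][:, 1])) < 1e-12)
    assert abs(exact_zero - 24) <= 2


def test_markers_static_when_no_motion():
    n = 100
    series = gd.JointAngleSeries(100.0, {"right": np.full((n, 3), 7.0)})
    rec = gd.angles_to_markers(series, pelvis_speed=0.0)
    for arr in rec.markers.values():
        assert np.ptp(arr, axis=0).max() < 1e-12


def test_sacrum_travels_speed_times_time():
    n = 1000  # 10 s at 100 Hz
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.25, 100.0).angles["right"]
    tiled = np.tile(cyc, (8, 1))
    series = gd.JointAngleSeries(100.0, {"right": tiled})
    rec = gd.angles_to_markers(series, pelvis_speed=0.65)
    x = rec.marker("sacrum")[:, 0]
    assert x[-1] - x[0] == pytest.approx(0.65 * (n - 1) / 100.0, abs=1e-9)


def test_knee_angle_recoverable_from_marker_vectors():
    """Inverse-geometry oracle: knee angle re-derived from thigh/shank vectors."""
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0).angles["right"]
    tiled = np.tile(cyc, (3, 1))
    rec = gd.angles_to_markers(gd.JointAngleSeries(100.0, {"right": tiled}), pelvis_speed=0.5)
    thigh = rec.marker("knee", "right") - rec.marker("hip", "right")
    shank = rec.marker("ankle", "right") - rec.marker("knee", "right")
    th_t = np.degrees(np.arctan2(thigh[:, 0], -thigh[:, 2]))
    th_s = np.degrees(np.arctan2(shank[:, 0], -shank[:, 2]))
    assert np.max(np.abs((th_t - th_s) - tiled[:, 1])) < 0.5


def test_cohort_deterministic_for_fixed_seed():
    cfg = gd.SyntheticConfig(n_participants=2, n_trials_per_condition=1, seed=5)
    t1, g1 = gd.generate_cohort(cfg)
    t2, g2 = gd.generate_cohort(cfg)
    assert len(t1) == len(t2)
    for a, b in zip(t1, t2):
        for name in a.markers:
            assert np.array_equal(a.markers[name], b.markers[name])
    assert list(g1.trials) == list(g2.trials)
    for tid in g1.trials:
        assert g1.trials[tid] == g2.trials[tid]


def test_cohort_counts_and_annotations(clean_cohort):
    cfg, trials, truth = clean_cohort
    expected = cfg.n_participants * len(cfg.conditions) * cfg.n_trials_per_condition
    assert len(trials) == expected == len(truth.trials)
    for tid, tt in truth.trials.items():
        for side in ("left", "right"):
            fc = np.asarray(tt.foot_contacts[side])
            assert np.all(np.diff(fc) > 0)
            assert len(tt.cycles[side]) == cfg.strides_per_trial
        assert 0.15 <= tt.speed <= 1.4
        for v in tt.pause_fractions_pairs.values():
            assert 0.0 <= v <= 1.0


def test_ground_truth_json_round_trip(tmp_path, clean_cohort):
    _, _, truth = clean_cohort
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = gd.GroundTruth.from_json(path)
    assert back.trials == truth.trials


def test_pair_to_joint_pause_solver_is_consistent():
    pairs = {"hip_knee": 0.161, "hip_ankle": 0.137, "knee_ankle": 0.217}
    joints = pair_to_joint_pauses(pairs)
    assert joints["hip"] + joints["knee"] == pytest.approx(pairs["hip_knee"], abs=1e-9)
    assert joints["hip"] + joints["ankle"] == pytest.approx(pairs["hip_ankle"], abs=1e-9)
    assert joints["knee"] + joints["ankle"] == pytest.approx(pairs["knee_ankle"], abs=1e-9)
    assert all(v >= 0 for v in joints.values())


def test_comfort_scores_shape_and_range():
    scores = gd.generate_comfort_scores(16, seed=0)
    assert scores.shape == (16, 3)
    assert ((scores >= 0) & (scores <= 10)).all().all()
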
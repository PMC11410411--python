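"""Decomposition index: velocity, pause masks, pair indices, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gaitdecomp as gd
from gaitdecomp.decomposition import angular_velocity, decomposition_index, pause_mask
from gaitdecomp.exceptions import DomainError, GaitError
from conftest import HEALTHY_MAXIMA


# --- angular velocity -------------------------------------------------------

def test_constant_angle_has_zero_velocity():
    v = angular_velocity(np.full((100, 1), 12.0), 100.0, None)
    assert np.max(np.abs(v)) == 0.0


def test_ramp_velocity_closed_form():
    y = 0.5 * np.arange(200)  # 0.5 deg/frame at 100 Hz -> 50 deg/s
    v = angular_velocity(y[:, None], 100.0, None)
    assert np.allclose(v, 50.0)


def test_sinusoid_peak_velocity_matches_analytic_derivative():
    rate, f, amp = 100.0, 1.0, 30.0
    t = np.arange(600) / rate
    y = amp * np.sin(2 * np.pi * f * t)
    v = angular_velocity(y[:, None], rate, 6.0)[:, 0]
    peak = np.max(np.abs(v[50:-50]))
    assert peak == pytest.approx(2 * np.pi * f * amp, rel=0.02)


def test_velocity_needs_three_samples():
    with pytest.raises(DomainError):
        angular_velocity(np.zeros((2, 1)), 100.0)


# --- pause masks ------------------------------------------------------------

def test_frozen_joint_rule_marks_whole_cycle_paused():
    m = pause_mask(np.zeros(120), None, 0.05, 1.0)
    assert m.paused.all()
    assert m.baseline_velocity == 0.0


def test_threshold_is_fraction_of_cycle_peak():
    v = np.linspace(-100, 100, 201)
    m = pause_mask(v, None, 0.05, 1.0)
    assert m.threshold == pytest.approx(5.0)
    assert np.array_equal(m.paused, np.abs(v) < 5.0)


def test_pause_fraction_domain():
    with pytest.raises(DomainError):
        pause_mask(np.ones(10), None, 0.0, 1.0)
    with pytest.raises(DomainError):
        pause_mask(np.ones(10), None, 1.0, 1.0)


@given(scale=st.floats(0.1, 50.0))
def test_pause_mask_is_scale_invariant(scale):
    rng = np.random.default_rng(4)
    v = rng.normal(0, 10, 150)
    a = pause_mask(v, None, 0.05, 0.0)
    b = pause_mask(scale * v, None, 0.05, 0.0)
    assert np.array_equal(a.paused, b.paused)


# --- decomposition index ----------------------------------------------------

def test_simultaneous_sinusoids_give_zero_index():
    t = np.arange(120) / 120.0
    y = 20 * np.sin(2 * np.pi * t)
    v = angular_velocity(np.column_stack([y, y]), 100.0, 6.0)
    a = pause_mask(v[:, 0], None, 0.05, 1.0)
    b = pause_mask(v[:, 1], None, 0.05, 1.0)
    assert decomposition_index(a, b) == 0.0


def test_one_moving_one_frozen_gives_hundred():
    t = np.arange(120) / 120.0
    moving = 20 * np.sin(2 * np.pi * t)
    frozen = np.full(120, 7.0)
    v = angular_velocity(np.column_stack([moving, frozen]), 100.0, 6.0)
    a = pause_mask(v[:, 0], None, 0.05, 1.0)
    b = pause_mask(v[:, 1], None, 0.05, 1.0)
    assert decomposition_index(a, b) == 100.0


def test_mask_example_twenty_percent():
    a = np.zeros(120, dtype=bool)
    a[:24] = True
    b = np.zeros(120, dtype=bool)
    assert decomposition_index(a, b) == pytest.approx(20.0)


def test_length_mismatch_is_an_error():
    with pytest.raises(GaitError):
        decomposition_index(np.zeros(10, dtype=bool), np.zeros(12, dtype=bool))


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=20))
def test_index_equals_brute_force_enumeration(pairs):
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    one = sum(1 for x, y in pairs if x != y)
    moving = sum(1 for x, y in pairs if not (x and y))
    expected = 100.0 * one / moving if moving else 0.0
    assert decomposition_index(a, b) == pytest.approx(expected, abs=1e-12)
    # symmetry and bounds
    assert decomposition_index(b, a) == decomposition_index(a, b)
    assert 0.0 <= decomposition_index(a, b) <= 100.0


def test_offset_invariance_of_index():
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, 1.2, 100.0)
    shifted = cyc.copy()
    shifted.angles["right"] = shifted.angles["right"] + np.array([13.0, -5.0, 40.0])
    shifted.angles["right"] = np.clip(shifted.angles["right"], -180, 180)
    d1 = gd.decomposition_all_pairs(cyc, [(0, 120)], filter_cutoff=None).trial_means
    d2 = gd.decomposition_all_pairs(shifted, [(0, 120)], filter_cutoff=None).trial_means
    for pair in d1:
        assert d2[pair] == pytest.approx(d1[pair], abs=1e-9)


def test_all_joints_frozen_gives_zero_indices():
    still = gd.JointAngleSeries(100.0, {"left": np.full((120, 3), 3.0)})
    res = gd.decomposition_all_pairs(still, [(0, 120)])
    assert res.trial_means == {"hip_knee": 0.0, "hip_ankle": 0.0, "knee_ankle": 0.0}


def test_injected_knee_pause_raises_knee_pairs_only():
    """Pausing the knee inflates hip-knee and knee-ankle above the natural
    baseline by ~the injected fraction, leaving hip-ankle unchanged."""
    n = 154

    def indices(frac):
        cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, n / 100.0, 100.0)
        if frac:
            cyc = gd.inject_pause(cyc, "knee", frac, placement=0.55)
        return gd.decomposition_all_pairs(cyc, [(0, n)], filter_cutoff=None).trial_means

    base = indices(0.0)
    got = indices(0.2)
    assert got["hip_knee"] - base["hip_knee"] == pytest.approx(20.0, abs=2.0)
    assert got["hip_ankle"] == pytest.approx(base["hip_ankle"], abs=2.0)
    assert got["knee_ankle"] > base["knee_ankle"] + 10.0


def test_recovery_is_monotone_in_injected_fraction():
    n = 154
    out = []
    for frac in (0.0, 0.1, 0.2, 0.3):
        cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, n / 100.0, 100.0)
        if frac:
            cyc = gd.inject_pause(cyc, "knee", frac, placement=0.55)
        out.append(
            gd.decomposition_all_pairs(cyc, [(0, n)], filter_cutoff=None).trial_means["hip_knee"]
        )
    assert all(b >= a for a, b in zip(out, out[1:]))


def test_healthy_template_indices_stay_at_or_below_ten_percent():
    n = 154
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, n / 100.0, 100.0)
    tiled = np.tile(cyc.angles["right"], (6, 1))
    series = gd.JointAngleSeries(100.0, {"right": tiled})
    res = gd.decomposition_all_pairs(series, [(2 * n, 3 * n)])
    for pair, val in res.trial_means.items():
        assert val <= 10.0
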
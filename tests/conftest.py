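import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitdecomp as gd

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Healthy-walking sagittal maxima (degrees) used as the reference template.
HEALTHY_MAXIMA = {"hip": 30.0, "knee": 60.0, "dorsiflexion": 15.0, "plantarflexion": 20.0}


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free cohort with ground truth (3 participants, 1 trial/cond)."""
    cfg = gd.SyntheticConfig(
        n_participants=3, n_trials_per_condition=1, noise_sd_marker=0.0, seed=11
    )
    trials, truth = gd.generate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort with the default 2 mm marker noise."""
    cfg = gd.SyntheticConfig(n_participants=3, n_trials_per_condition=1, seed=7)
    trials, truth = gd.generate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def healthy_trial():
    """Noise-free two-legged walking trial built from the healthy template."""
    n = 120
    cyc = gd.generate_angle_cycle(HEALTHY_MAXIMA, n / 100.0, 100.0)
    arr = cyc.angles["right"]
    tiled = np.tile(arr, (6, 1))
    right = np.roll(tiled, 36, axis=0)
    left = np.roll(tiled, 36 + 60, axis=0)
    series = gd.JointAngleSeries(100.0, {"left": left, "right": right})
    return gd.angles_to_markers(series, pelvis_speed=0.65), tiled


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Default-scale end-to-end pipeline run (16 participants, 4x3 trials)."""
    out = tmp_path_factory.mktemp("fullrun")
    payload = gd.run_all(gd.RunConfig(), out, seed=42)
    return out, payload
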
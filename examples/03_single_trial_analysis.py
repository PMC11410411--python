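"""Full single-trial analysis: events, angles, spatiotemporal metrics.

Generates one noise-free trial with known ground truth, runs the detection
and measurement chain, and compares estimates with the truth.
"""

import numpy as np

import gaitdecomp as gd

cfg = gd.SyntheticConfig(
    n_participants=1, n_trials_per_condition=1, noise_sd_marker=0.0, seed=3
)
trials, truth = gd.generate_cohort(cfg)
rec = trials[0]
tt = truth.trials[next(iter(truth.trials))]
side = rec.paretic_side

events = gd.detect_events(rec)
print(f"paretic ({side}) foot contacts: detected {[int(f) for f in events.sides[side].foot_contacts]}")
print(f"                                   true {tt.foot_contacts[side]}")

angles = gd.compute_sagittal_angles(rec)
st = gd.spatiotemporal(rec, events, side=side)
print(f"\ngait velocity : {np.mean(st.per_cycle['gait_velocity']):.3f} m/s "
      f"(true {tt.speed:.3f})")
for m in ("step_length", "step_width", "double_support", "foot_clearance"):
    unit = "%" if m == "double_support" else "m"
    print(f"{m:14s}: {st.means[m]:.3f} {unit}")

km = gd.kinematic_maxima(angles, events.cycles(side)[1], side=side)
print("\nper-cycle sagittal maxima (measured vs generated):")
for name, true_key in [
    ("max_hip_flexion", "hip"),
    ("max_knee_flexion", "knee"),
    ("max_ankle_dorsiflexion", "dorsiflexion"),
    ("max_ankle_plantarflexion", "plantarflexion"),
]:
    print(f"  {name:26s} {km.as_dict()[name]:6.2f}  vs {tt.joint_maxima[true_key]:6.2f} deg")

res = gd.decomposition_all_pairs(angles, events.cycles(side), side=side)
print("\ndecomposition indices (measured | injected pair pause):")
for pair, val in res.trial_means.items():
    print(f"  {pair:11s} {val:5.1f} % | {100 * tt.pause_fractions_pairs[pair]:5.1f} %")
print("\nMeasured indices track the injected pauses plus the small natural")
print("dwell every joint shows at its movement reversals.")
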
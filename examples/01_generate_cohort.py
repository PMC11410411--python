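"""Generate a small synthetic foot-drop cohort and inspect its ground truth.

Builds 2 participants x 4 walking conditions x 1 trial with the default
study parameters (100 Hz, ~0.65 m/s, condition-dependent ROM and pause
structure), writes one trial in the canonical CSV dialect, and prints what
the generator knows to be true about it.
"""

from pathlib import Path
from tempfile import mkdtemp

import gaitdecomp as gd

cfg = gd.SyntheticConfig(n_participants=2, n_trials_per_condition=1, seed=42)
trials, truth = gd.generate_cohort(cfg)
print(f"generated {len(trials)} trials "
      f"({cfg.n_participants} participants x {len(cfg.conditions)} conditions)")

rec = trials[0]
tid = next(iter(truth.trials))
tt = truth.trials[tid]
print(f"\ntrial {tid}: paretic side = {tt.paretic_side}, "
      f"true speed = {tt.speed:.3f} m/s, cycle = {tt.cycle_frames} frames")
print(f"true foot contacts ({tt.paretic_side}): {tt.foot_contacts[tt.paretic_side]}")
print(f"true paretic maxima (deg): " +
      ", ".join(f"{k}={v:.1f}" for k, v in tt.joint_maxima.items()))
print(f"injected pair pause fractions: " +
      ", ".join(f"{k}={v:.3f}" for k, v in tt.pause_fractions_pairs.items()))

out = Path(mkdtemp()) / f"{tid}.csv"
gd.write_trial(rec, out)
print(f"\nwrote {out} ({out.stat().st_size // 1024} KB)")
print("The pause fractions are what the decomposition stage should recover;")
print("the maxima are what the kinematics stage should recover.")
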
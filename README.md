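# gaitdecomp

Quantitative gait analysis for foot-drop research: from 3D marker
trajectories (or sagittal joint-angle series) to spatiotemporal gait
parameters, sagittal kinematic maxima, the **interjoint decomposition
index**, and condition-comparison statistics — with a fully seeded
synthetic-cohort generator, so every stage of the pipeline can be exercised
and validated against known ground truth without access to patient
recordings.

Foot drop — weakness of the ankle dorsiflexors, typically after stroke,
multiple sclerosis or peroneal neuropathy — impairs swing-phase foot
clearance and is commonly managed with an ankle-foot orthosis (AFO) or an
elastic-band assistive harness. Comparing such devices requires more than
speed and step measures: a rigid orthosis may restore clearance while
*degrading* interjoint coordination. The decomposition index captures that.

## The decomposition index

For a pair of joints over one gait cycle, a joint counts as **paused** at a
frame when its angular velocity magnitude drops below 5% of that joint's
peak angular velocity within the cycle (an absolute floor of 1 deg/s
handles joints that barely move at all). The index is

```
D = 100 · #{frames where exactly one joint is paused}
        / #{frames where at least one joint moves}     [%]
```

`D = 0%` means the two joints always move simultaneously; `D = 100%` means
motion occurs strictly one joint at a time. Frames where both joints are
paused say nothing about interjoint *sequencing* and are excluded from the
reference duration. The index is computed per cycle for the three pairs
hip–knee, hip–ankle and knee–ankle of the paretic leg, then averaged over
cycles and trials. Healthy comfortable walking shows ~5–10%; neurologically
impaired gait can exceed 20%.

The surrounding pipeline provides:

* **synthetic** — seeded cohort generator: Fourier-template joint angles,
  per-joint pause injection, planar forward kinematics to a 13-marker set,
  per-participant/condition effects, full ground-truth annotation;
* **trial_io** — strict canonical CSV dialect and TRC import/export, YAML
  run configuration;
* **events** — coordinate-based (sacrum-relative) foot-contact / toe-off
  detection and cycle segmentation;
* **metrics** — planar sagittal inverse kinematics; gait velocity, step
  length/width, double support, foot clearance, per-cycle joint maxima;
* **decomposition** — pause masks and pair indices as defined above;
* **stats** — cycle→trial→condition averaging, KS normality check, one-way
  ANOVA (df (3, 60) for 16 participants × 4 conditions) with Tukey HSD and
  partial η², Bonferroni-adjusted paired t-tests for comfort ratings;
* **pipeline / CLI** — `gaitdecomp simulate | analyze | stats | run-all`
  with manifests and deterministic reruns.

## Worked example

`examples/02_decomposition_index.py` evaluates the index on its two
boundary cases and on the healthy-walking template:

```
two joints moving in phase      -> D =   0.00 %
one moving, one frozen          -> D = 100.00 %
healthy gait template           -> hip_knee=5.8%, hip_ankle=5.2%, knee_ankle=5.8%
```

In-phase motion yields exactly 0%, a frozen joint against a moving one
exactly 100%, and the healthy template sits inside the 5–10% window
expected for comfortable walking.

`examples/03_single_trial_analysis.py` runs the full chain on one
noise-free synthetic trial and compares estimates with the generator's
ground truth:

```
paretic (left) foot contacts: detected [123, 275, 427, 579, 731]
                                   true [123, 275, 427, 579, 731]

gait velocity : 0.669 m/s (true 0.669)
...
decomposition indices (measured | injected pair pause):
  hip_knee     14.6 % |  17.8 %
  hip_ankle    18.4 % |  18.8 %
  knee_ankle   21.1 % |  21.0 %
```

Events are recovered exactly, speed to three decimals, and the indices
track the injected pause structure (plus each joint's small natural dwell
at movement reversals). `examples/04_condition_statistics.py` runs the
cohort-level statistics; the decomposition metrics carry the largest
condition effects (partial η² ≈ 0.4–0.6, "large"), with the AFO raising
and the elastic-harness conditions lowering the indices — the pattern the
index is designed to expose.

A shell workflow for the same thing:

```bash
gaitdecomp run-all --seed 42 --out run/
# run/metrics.csv, run/stats/stats.json, run/stats/summary_table.csv
```

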
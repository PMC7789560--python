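# reachsim

Desk-scale simulation of **goal-context-aware control of a trans-humeral
prosthesis emulation**: can the four distal joint angles of an arm (elbow
flexion, forearm pronation-supination, wrist deviation and extension) be
predicted from the three residual shoulder angles alone — and how much
better does prediction and closed-loop control get when the predictor also
knows *where the movement goal is*?

The package is written for motor-control and neuroprosthetics researchers
who want a fully synthetic, reproducible test bed for proximal-to-distal
joint-angle prediction. It simulates the entire experiment end to end:

* a **7-DoF kinematic arm** (three segments, spherical joints) with
  forward kinematics, angle extraction from segment orientations, and a
  damped-least-squares inverse-kinematics solver with a comfort-posture
  null-space cost;
* a **pick-and-place task environment**: 50 grid positions (5×5×2, 8 cm
  pitch) × 5 frontal-plane tilts, constrained random target orders,
  a 6-D target zone (spatial + angular tolerance), 1 s hold-to-complete,
  15 s timeout;
* a **synthetic subject** that generates naturalistic reaching
  recordings at 90 Hz (minimum-jerk joint trajectories, filtered motor
  noise, target-dependent redundancy resolution) and a closed-loop user
  model that drives the shoulder and recruits compensatory trunk motion
  when distal predictions fail it;
* two **MLP regressors** (architecture 256–256–dropout 0.5–64–4):
  context-unaware **C−** (inputs: 3 shoulder angles) and context-aware
  **C+** (inputs: 3 shoulder angles + shoulder-to-target vector + target
  tilt);
* the **evaluation machinery**: offline RMSE, approach time/speed,
  shoulder-spread ellipsoid volume `SV = 36π σ₁σ₂σ₃`, per-trial average
  reaching postures, PCA synergy subspaces and principal angles between
  them, and the ANOVA/Kruskal–Wallis + paired post hoc statistical
  scaffold with Bonferroni correction (α_corr = 0.05/3 = 0.0167).

## Worked example

```python
import numpy as np
from reachsim import (
    ArmGeometry, SubjectParams, Tolerance, build_target_grid,
    build_target_set, generate_target_order, simulate_phase_natural,
    build_dataset, train, offline_rmse, Hyperparameters,
)

geometry = ArmGeometry()                       # 0.30/0.25/0.08 m segments
grid = build_target_grid(geometry)             # 50 positions
whole = build_target_set(grid, "whole")        # 250 targets
order = generate_target_order(whole, 200, seed=1)

subject = SubjectParams(seed=3, context_coupling=1.0)
rec, outcomes = simulate_phase_natural(
    order, Tolerance(0.02, 5.0), subject, geometry, np.random.default_rng(3)
)
print(len(order.sequence), np.mean([o.success for o in outcomes]))

hyper = Hyperparameters(max_epochs=120, patience=15, max_train_rows=6000)
for mode in ("C+", "C-"):
    ds = build_dataset(rec, mode)
    model = train(ds, hyper, seed=11)
    print(mode, round(offline_rmse(model, ds).pooled, 2))
```

Output from this exact script:

```
248 1.0
C+ 2.9
C- 9.68
```

248 trials were simulated (the constrained draw from 250 targets
dead-ends near the end), every trial succeeded, and the context-aware
network predicts the four distal angles with 2.9° pooled RMSE against
9.68° for the context-unaware one — the central effect: shoulder angles
alone under-determine the distal posture once the subject's coordination
depends on the goal.

The full five-phase protocol (acquisition → training → two
counterbalanced hybrid test phases → natural baseline, then metrics,
synergies and statistics) runs from a config:

```bash
reachsim run-all --seed 0 --out runs/demo     # toy 2-subject config
```

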
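# Methods

## The simulated system

The package emulates, entirely in software, an experiment in which a
seated subject performs pick-and-place movements with a virtual arm while
the arm's four distal degrees of freedom are driven either by the
subject (natural control, N) or by a neural-network predictor fed with
the subject's three shoulder angles, without (C−) or with (C+) contextual
knowledge of the movement goal.

### Arm model

Three rigid segments (upper arm 0.30 m, forearm 0.25 m, wrist-to-hand
center 0.08 m by default; configurable per subject) connected by
spherical joints, of which seven rotations are used: shoulder
flexion-extension, abduction-adduction, humeral axial rotation, elbow
flexion, forearm pronation-supination, wrist radial-ulnar deviation and
flexion-extension.

World frame: x anterior, y left, z up; the subject faces +x. In the
neutral posture (all angles zero) the arm hangs at the side, every
segment frame coincides with the world frame, and segments extend along
local −z. Rotations compose intrinsically:

    R_upper = Ry(−sh_flex) · Rx(sh_abd) · Rz(hum_rot)
    R_fore  = R_upper · Ry(−el_flex) · Rz(for_sup)
    R_hand  = R_fore · Ry(−wr_ext) · Rx(wr_dev)

The Euler singularity sits at |sh_abd| = 90°, at the edge of the grid
workspace; angle extraction resolves it by convention (hum_rot = 0,
flexion absorbs the remainder) and otherwise returns the unique
|sh_abd| ≤ 90° factorization. The grasp axis — the direction that must
align with a target's tilt — is the hand-frame vector that is vertical
in the neutral posture.

Joint limits (deg): sh_flex [−60, 170], sh_abd [−30, 120],
hum_rot [−90, 90], el_flex [0, 150], for_sup [−85, 85],
wr_dev [−30, 20], wr_ext [−85, 85]. These are standard anatomical
ranges; the wrist flexion-extension range is set at ±85° (the upper end
of published ranges) because with the grasp axis fixed in the hand frame,
reaching the lowest grid row with a near-vertical bottle requires close
to 85° of wrist flexion — the apparatus is configured, as any such
protocol must be, so that every target is comfortably reachable. This
was verified by solving the inverse kinematics for all 250 targets.

### Inverse kinematics

Damped least squares on the stacked 6-D error (3-D position; the
component of the goal axis orthogonal to the current grasp axis, weighted
0.2 m/rad), with an analytic geometric Jacobian. The damping is annealed
with the residual (λ = clip(residual, 1e-4, 0.05) m) so the step
approaches Gauss-Newton near the solution; joints pinned at a limit and
pushing outward are removed from the task Jacobian (gradient
projection); a null-space step descends the weighted squared deviation
from a configurable comfort posture, capped at half the task step so the
two cannot limit-cycle. Default tolerances {1 mm, 0.5°}, 500 iterations,
and a fixed pool of deterministic restarts; the solver is a pure
function of its inputs. Goals beyond the 0.63 m reach radius raise an
`unreachable` error.

### Task environment

Targets on a 5 (high) × 5 (wide) × 2 (deep) lattice, 8 cm pitch, near
face 0.24 m anterior of the shoulder, laterally and vertically centered
on it — 50 positions, all reachable; five frontal-plane tilts
{−45, −22.5, 0, 22.5, 45}°. The whole set (250 targets) is used for data
acquisition at tolerance {2 cm, 5°}; the subset (120 targets over the 24
positions that survive removing the leftmost and rightmost columns and
the lowest row) at {4 cm, 10°} for test and baseline phases. Random
orders alternate pick/place roles and forbid consecutive targets at
26-neighborhood-adjacent grid positions; draws are without replacement
and regenerate wholesale (seed+1) when they dead-end below the minimum
length. A trial succeeds at the first sample by which the hand has been
inside the 6-D zone continuously for 1 s (span on the 90 Hz grid) and
times out 15 s after trial start. The hand is never reset: each trial
starts where the last one ended. Axis alignment is unsigned (a bottle is
symmetric under flip); zone boundaries are closed.

### Synthetic subject — natural control

For each target, a goal posture is obtained by the IK solver from a fixed
comfort-posture init, so redundancy is resolved consistently: the same
target always yields the same posture. `context_coupling` ∈ [0,1]
controls how much goal information the *shoulder* carries. At coupling 0
the solver distributes tilt compensation across all seven joints, so the
shoulder angles themselves encode the goal and remain a sufficient
predictor input (the internal negative control). At coupling c > 0 the
solve is anchored to the posture the subject adopts for the target
*position* at neutral tilt (solved once per position) and the shoulder's
step share in the solver is scaled by (1 − 0.9c), so tilt compensation
lands in the distal joints except for the residual they cannot absorb;
in addition the distal comfort target is shifted by a smooth **bias
map** of the target's tilt and position (magnitude up to 15° at
coupling 1). The result is the study's premise made literal: at full
coupling, targets that put the shoulder in (nearly) the same place
demand visibly different distal postures, so shoulder angles alone
cannot disambiguate them — exactly the information the contextual
inputs restore. Empirically the offline C−−C+ RMSE gap grows
monotonically with the coupling.

The time course is minimum-jerk (10τ³−15τ⁴+6τ⁵) in joint space, duration
max(0.4 s, 2.5 s/m × hand-to-target distance), followed by a ≥1.2 s
dwell; i.i.d. Gaussian motor noise (SD 1° default) low-passed at 5 Hz
(2nd-order Butterworth, zero phase) is added per joint and sample. Only
the terminal dwell matters for training data (in-zone filtering). The
shoulder center translates with the target (gain 0.05 per unit offset
from the grid center, ≈8 mm SD across targets), emulating the scapular
motion naturally involved in reaching; this keeps the natural-control
spread volume small but nonzero, as observed for intact reaching.

### Synthetic subject — hybrid control (closed loop)

During test phases the displayed arm combines the user's commanded
shoulder angles with the predictor's four distal angles. The user model
updates its shoulder command each sample (90 Hz) with

* a **feedforward** pull (0.018/sample) toward the shoulder angles of
  the subject's natural goal posture for the target — the coordination an
  intact arm would use;
* a **feedback** damped-least-squares step (0.05/sample) on the 6-D
  hand-pose error computed through the composite map
  FK ∘ [shoulder ↦ (shoulder, predict(shoulder[, context]))], with the
  Jacobian estimated by forward differences (0.5°) through the actual
  predictor;
* a step cap of 0.8°/sample (72°/s), below natural movement speed:
  untrained users under novel hybrid control move deliberately.

Compensatory **trunk translation** (bounded at 0.25 m, seated subject)
engages at 2 mm per sample per unit normalized residual only when the
error has plateaued (<1% improvement over 0.5 s) while outside the target
zone, relaxes toward the backrest (×0.995/sample) while holding inside
the zone, and freezes if the error diverges to 10× its trial-start
value. These gains were calibrated once so that a good predictor yields
success within the 15 s budget at human-plausible approach times slower
than natural control, and then frozen.

In parallel, a **mimicked stream** tracks what natural control would have
displayed for the same commanded shoulder angles: a warm-started
distal-only DLS tracker (1 iteration/sample) toward the target pose
with the comfort-bias attractor in its null space. Displayed and
mimicked streams share shoulder angles sample by sample; the mimicked
distal angles feed the MC+/MC− posture groups.

### Datasets and predictors

Training rows are the in-zone samples of a recording. C− inputs are the
three shoulder angles; C+ additionally receives the shoulder-to-target
vector in a frame translated to the instantaneous shoulder center (axes
parallel to the world frame — the seated subject faces a fixed
direction) plus the target tilt. Outputs are the four distal angles of
the same sample. Angles are in degrees and distances in meters in the
stored datasets; per-feature standardization (training-set mean/SD) is
applied inside the predictor.

The regressor is a fixed MLP — input (3 or 7) → dense 256 (ReLU) →
dense 256 (ReLU) → dropout 0.5 (training only) → dense 64 (ReLU) →
linear 4 — trained with Adam (lr 1e-3, batch 64) on the MSE of
standardized outputs, early stopping (patience 20 default) on a 10%
validation split, deterministic per seed. The backend is a compact numpy
implementation behind an exchangeable interface; numerically checked
gradients, He initialization, inverted dropout. Predictions are clamped
to the distal joint limits before display (the virtual arm must remain
anatomical), which is inactive for realistic angle data. Dwell samples
are highly redundant (≈100 near-identical rows per trial), so training
may subsample to a row cap (`max_train_rows`) without information loss.

### Metrics

* **Approach time (AT)**: trial start → first zone entry; defined only
  for zone-entered trials.
* **Approach speed (AS)** = start-hand-to-target distance / AT, in cm/s,
  with AT floored at one sample period. The start reference is the hand
  center at trial start.
* **Shoulder spread volume (SV)** = 36π σ₁σ₂σ₃ over the principal-axis
  SDs of the shoulder-position sample covariance (n−1), in cm³;
  rotation- and translation-invariant; the 3-SD ellipsoid holds
  χ²₃(9) ≈ 97.07% of a trivariate normal's mass (the reported coverage
  fraction is a diagnostic).
* **Average reaching postures**: per-trial means of the seven angles
  over the last in-zone run; sample SDs (n−1) across trials quantify
  posture variability per phase.

### Synergy analysis

PCA (mean-centered, unscaled — all seven dimensions are degrees) on the
average reaching postures of each group (N, C+, C−, MC+, MC−) yields
seven components and explained-variance ratios. The distance between the
subspaces spanned by the first n components of two groups is the
**largest principal angle** between the spans (computed from the SVD of
the inner-product matrix of orthonormal bases): 0° iff the spans
coincide, 90° for orthogonal subspaces, symmetric, and invariant to any
orthonormal re-basis of either span. The informative range is n = 3–5
(below 3 PCs the subspace misses variance; above 5 the reduction is
moot); other n values are allowed with a warning.

### Statistics

Per-subject condition means are compared with one-way ANOVA when every
sample passes Shapiro–Wilk normality and the set passes median-centered
Levene homoscedasticity at α = 0.05, otherwise Kruskal–Wallis. A
significant omnibus is followed by paired T-tests (parametric path) or
exact two-sided Wilcoxon signed-rank tests at the Bonferroni-corrected
threshold α/3 = 0.0167. Offline C+ vs C− RMSE uses a two-sided paired
T-test. Zero-variance paired differences are reported as p = 0 with a
degeneracy flag rather than NaN.

### Protocol orchestration

Per subject: familiarization (simulated, unrecorded) → acquisition
(whole-set order, ≥200 trials, {2 cm, 5°}) → C+/C− training → two hybrid
test phases (subset order, {4 cm, 10°}), order counterbalanced across
subjects (even-indexed subjects start with C+) → natural baseline
(same subset order and test tolerances). All RNG streams are namespaced
from the config's master seed and per-subject seeds; a rerun reproduces
every output file byte for byte, and the run manifest stores SHA-256
hashes of all artifacts.

## Problem sizes

The default experiment scale follows the protocol (orders of ≥200
whole-set / ≥100 subset trials; a human study of this design would use
on the order of ten subjects). The package's own studies use desk-scale
sizes chosen for a single CPU:
the directional study runs five synthetic subjects with 150-trial
acquisition and 30-trial test/baseline orders, MLP training capped at
80 epochs / 5000 rows; the toy end-to-end configuration
(`reachsim.config.toy_config`) runs two subjects with 15/6-trial
orders. Directional conclusions are insensitive to these sizes; absolute
metric values are not, and the package never treats them as estimates of
what human subjects would produce.

## What the generator does and does not emulate

The synthetic subject produces: consistent target-dependent redundancy
resolution, smooth minimum-jerk reaches with filtered motor noise,
scapular shoulder translation, deliberate closed-loop shoulder control
under hybrid conditions, and instruction-compliant trunk compensation.
It does not emulate: learning or adaptation across trials, fatigue,
grasp/finger kinematics, trunk rotation (the egocentric frame only
translates), scapulo-humeral rhythm, tracker noise or calibration error,
or the true — unknown — form of human context-dependent coordination
(`context_coupling` is an explicit knob, not an estimate of the human
value). Tests passing on this generator therefore demonstrate that the
pipeline recovers the directional effects *when the generating process
matches the model's premise*, not that the premise holds in humans.

## Known limitations

* The grasp axis is rigidly attached to the hand segment; a real hand
  reorients a grasped cylinder with its fingers. This makes low, far,
  near-vertical targets the hardest of the workspace.
* The IK comfort cost induces one specific redundancy-resolution policy;
  humans vary across repetitions and individuals.
* The hybrid user model is a local feedback law; it cannot reproduce
  exploratory or strategic behavior (e.g. deliberately re-approaching a
  target from a different direction).
* With a well-performing C+ predictor the synthetic user rarely leaves
  the backrest, so SV(C+) is close to SV(N) rather than strictly between
  SV(N) and SV(C−); the separation that is robust — and tested — is
  SV(C−) above the other two conditions.
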
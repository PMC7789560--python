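"""Synthetic subject: naturalistic reaching generator + closed-loop user model.

This module replaces the human participant (and the VR apparatus) in two
ways:

* **Natural control** (:func:`natural_reach`, :func:`simulate_phase_natural`)
  generates full-arm reaching trajectories toward pick/place targets:
  a per-target goal posture from the IK solver with a comfort-posture
  attractor, a minimum-jerk time course in joint space, low-pass-filtered
  Gaussian motor noise, and a small target-dependent translation of the
  shoulder center emulating the scapular motion naturally involved in
  reaching.

* **Hybrid control** (:func:`hybrid_step`, :func:`simulate_phase_hybrid`)
  emulates a user driving a prosthesis-like arm whose distal joints follow
  a predictor: the user commands the three shoulder angles by a damped
  error-feedback law on the 6-D hand-pose error computed through the
  composite map FK ∘ [shoulder ↦ (shoulder, predict(shoulder[, context]))],
  and recruits compensatory trunk translation only when shoulder-only
  progress has plateaued.

Goal-dependent redundancy is injected by biasing the comfort posture's
four distal angles with a smooth function of target tilt and position,
scaled by ``context_coupling``. At coupling 0 the distal goal depends on
the target only through the pose constraint itself; at coupling 1 targets
sharing a shoulder configuration demand visibly different distal postures,
which is exactly the information the contextual inputs carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .kinematics import (
    ArmGeometry,
    HandPose,
    JointPosture,
    _jacobian,
    _pose_error,
    axis_from_tilt,
    fk_batch,
    limits_array,
    solve_ik,
)
from .recording import ANGLE_COLS, MIM_COLS, MotionRecording
from .tasks import (
    DT,
    GRID_NEAR_FACE,
    GRID_SPACING,
    Target,
    TargetOrder,
    Tolerance,
    TrialMonitor,
    TrialOutcome,
    in_zone_batch,
)

DEFAULT_COMFORT = JointPosture(45.0, 15.0, -10.0, 70.0, 10.0, 0.0, 0.0)

#: peak magnitude (deg) of the distal comfort bias at context_coupling = 1
BIAS_SCALE = 15.0


@dataclass
class SubjectParams:
    """Parameters of one synthetic subject."""

    comfort_posture: JointPosture = DEFAULT_COMFORT
    posture_cost_weights: np.ndarray = field(default_factory=lambda: np.ones(7))
    motor_noise_sd: float = 1.0  # deg, before 5 Hz low-pass
    movement_speed_gain: float = 2.5  # movement seconds per meter of reach
    context_coupling: float = 1.0
    trunk_gain: float = 0.002  # m per step per unit normalized residual
    natural_shoulder_gain: float = 0.05  # scapular translation per unit target offset
    max_trunk_offset: float = 0.25  # m, seated subject against a backrest
    seed: int = 0

    def __post_init__(self):
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")
        if not 0.0 <= self.context_coupling <= 1.0:
            raise ValueError("context_coupling must lie in [0, 1]")
        self.posture_cost_weights = np.asarray(self.posture_cost_weights, float)


def _subject_meta(subject: "SubjectParams") -> dict:
    """JSON-serializable snapshot of a subject's parameters."""
    return {
        "comfort_posture": subject.comfort_posture.as_array().tolist(),
        "posture_cost_weights": subject.posture_cost_weights.tolist(),
        "motor_noise_sd": subject.motor_noise_sd,
        "movement_speed_gain": subject.movement_speed_gain,
        "context_coupling": subject.context_coupling,
        "trunk_gain": subject.trunk_gain,
        "natural_shoulder_gain": subject.natural_shoulder_gain,
        "max_trunk_offset": subject.max_trunk_offset,
        "seed": subject.seed,
    }


def grid_center(geometry: ArmGeometry) -> np.ndarray:
    """Center of the target lattice in the world frame."""
    return geometry.shoulder_home + np.array(
        [GRID_NEAR_FACE + GRID_SPACING / 2, 0.0, 0.0]
    )


def distal_bias(target: Target, subject: SubjectParams, geometry: ArmGeometry) -> np.ndarray:
    """Target-dependent bias (deg) on (el_flex, for_sup, wr_dev, wr_ext).

    A smooth deterministic function of the target's tilt and of its
    position relative to the grid center, with magnitude up to
    ``BIAS_SCALE`` at context_coupling = 1. This is the redundancy that
    shoulder angles alone cannot disambiguate.
    """
    u = target.tilt / 45.0
    p = np.clip((target.position - grid_center(geometry)) / 0.16, -1.0, 1.0)
    raw = np.array(
        [
            0.5 * u * (0.5 + 0.5 * p[2]),
            0.7 * u,
            0.4 * u * (0.5 + 0.5 * p[1]),
            0.5 * np.sin(np.pi * u / 2) * (0.5 + 0.5 * p[0]),
        ]
    )
    return BIAS_SCALE * subject.context_coupling * raw


def natural_shoulder_offset(
    target: Target, subject: SubjectParams, geometry: ArmGeometry
) -> np.ndarray:
    """Small scapular shoulder-center translation accompanying a reach."""
    return subject.natural_shoulder_gain * (target.position - grid_center(geometry))


def goal_posture(
    target: Target,
    subject: SubjectParams,
    geometry: ArmGeometry,
    _cache: dict | None = None,
) -> tuple[JointPosture, np.ndarray]:
    """Deterministic goal posture and shoulder position for one target.

    The IK runs from a fixed comfort-biased init so that redundancy is
    resolved consistently (the same target always yields the same posture,
    regardless of where the previous trial ended).

    ``context_coupling`` controls how much goal information the shoulder
    carries. At coupling 0 the solver distributes the tilt across all
    seven joints, so the shoulder angles themselves encode the goal and
    remain a sufficient predictor input. At coupling c > 0 the solve is
    anchored to the posture the subject adopts for the *position alone*
    and the shoulder's step share in the solver is scaled down by
    (1 − 0.9c): tilt compensation lands in the distal joints except for
    the residual they cannot absorb, and the distal comfort target is
    additionally shifted by the tilt/position bias map — so targets
    sharing a shoulder configuration demand different distal postures.
    """
    c = subject.context_coupling
    lim = limits_array()
    comfort = subject.comfort_posture.as_array()
    sh = geometry.shoulder_home + natural_shoulder_offset(target, subject, geometry)
    goal = HandPose(target.position, axis_from_tilt(target.tilt))
    bias = distal_bias(target, subject, geometry)
    full_key = None
    if _cache is not None:
        full_key = ("q", round(float(target.position[0]), 6),
                    round(float(target.position[1]), 6),
                    round(float(target.position[2]), 6), float(target.tilt))
        hit = _cache.get(full_key)
        if hit is not None:
            return JointPosture.from_array(hit), sh

    if c == 0:
        comfort_p = JointPosture.from_array(
            np.clip(comfort, lim[:, 0], lim[:, 1])
        )
        q = solve_ik(
            goal, geometry, sh, init=comfort_p,
            posture_cost_weights=subject.posture_cost_weights,
            comfort_posture=comfort_p,
        )
        if _cache is not None:
            _cache[full_key] = q.as_array()
        return q, sh

    # shoulder anchor: the posture this subject adopts for the position
    # alone (neutral tilt); the tilted pose is then solved with the
    # shoulder confined to a narrow box around the anchor so that tilt
    # compensation lands in the distal joints
    key = (round(float(target.position[0]), 6), round(float(target.position[1]), 6),
           round(float(target.position[2]), 6))
    q_pos_arr = _cache.get(key) if _cache is not None else None
    if q_pos_arr is None:
        base_comfort = JointPosture.from_array(
            np.clip(comfort, lim[:, 0], lim[:, 1])
        )
        q_pos_arr = solve_ik(
            HandPose(target.position, axis_from_tilt(0.0)),
            geometry,
            sh,
            init=base_comfort,
            posture_cost_weights=subject.posture_cost_weights,
            comfort_posture=base_comfort,
        ).as_array()
        if _cache is not None:
            _cache[key] = q_pos_arr
    anchor = q_pos_arr[:3]
    biased = np.concatenate([anchor, comfort[3:] + bias])
    biased = np.clip(biased, lim[:, 0], lim[:, 1])
    comfort_p = JointPosture.from_array(biased)
    # init already tilts the axis distally: supination ≈ frontal tilt for
    # a forward-pointing forearm
    init_arr = q_pos_arr.copy()
    init_arr[4] = np.clip(init_arr[4] + target.tilt, lim[4, 0], lim[4, 1])
    init_p = JointPosture.from_array(init_arr)
    # reluctant shoulder: down-scaled step share, recruited only for the
    # residual the distal joints cannot absorb
    scales = np.r_[np.full(3, 1.0 - 0.9 * c), np.ones(4)]
    q = solve_ik(
        goal, geometry, sh, init=init_p,
        posture_cost_weights=subject.posture_cost_weights,
        comfort_posture=comfort_p, dof_scales=scales,
    )
    if _cache is not None:
        _cache[full_key] = q.as_array()
    return q, sh


def minimum_jerk(n: int) -> np.ndarray:
    """The 10-15-6 minimum-jerk position profile on n samples, s(0)=0, s(1)=1."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, cols: int) -> np.ndarray:
    """I.i.d. Gaussian angle noise low-passed at 5 Hz (2nd-order Butterworth)."""
    if sd == 0 or n == 0:
        return np.zeros((n, cols))
    raw = rng.normal(0.0, sd, size=(n, cols))
    if n < 28:  # too short for filtfilt padding; leave unfiltered
        return raw
    sos = butter(2, 5.0, fs=1.0 / DT, output="sos")
    return sosfiltfilt(sos, raw, axis=0)


def natural_reach(
    start: JointPosture,
    start_shoulder: np.ndarray,
    target: Target,
    subject: SubjectParams,
    geometry: ArmGeometry,
    rng: np.random.Generator,
    dwell_s: float = 1.2,
    _cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, JointPosture]:
    """One natural reach: (n, 7) angle samples, (n, 3) shoulder positions.

    Minimum-jerk interpolation in joint space from ``start`` to the
    target's goal posture, duration max(0.4 s, movement_speed_gain x hand
    distance), followed by a terminal dwell of ``dwell_s`` inside the zone.
    Motor noise is added to every sample and low-pass filtered.
    """
    q_goal, sh_goal = goal_posture(target, subject, geometry, _cache=_cache)
    qg = q_goal.as_array()
    q0 = start.as_array()
    f0 = fk_batch(q0, geometry, start_shoulder)
    dist = float(np.linalg.norm(f0["hand_center"][0] - target.position))
    duration = max(0.4, subject.movement_speed_gain * dist)
    n_mov = max(2, int(round(duration / DT)))
    n_dwell = int(round(dwell_s / DT))
    s = minimum_jerk(n_mov)
    q_traj = q0 + s[:, None] * (qg - q0)
    sh_traj = np.asarray(start_shoulder) + s[:, None] * (
        sh_goal - np.asarray(start_shoulder)
    )
    q_traj = np.vstack([q_traj, np.tile(qg, (n_dwell, 1))])
    sh_traj = np.vstack([sh_traj, np.tile(sh_goal, (n_dwell, 1))])
    noise = _smooth_noise(rng, len(q_traj), subject.motor_noise_sd, 7)
    lim = limits_array()
    q_traj = np.clip(q_traj + noise, lim[:, 0], lim[:, 1])
    return q_traj, sh_traj, q_goal


def simulate_phase_natural(
    order: TargetOrder,
    tol: Tolerance,
    subject: SubjectParams,
    geometry: ArmGeometry,
    rng: np.random.Generator,
    phase: str = "acquisition",
    hold_s: float = 1.0,
    timeout_s: float = 15.0,
) -> tuple[MotionRecording, list[TrialOutcome]]:
    """Run a whole natural-control phase, chaining trials without reset."""
    import pandas as pd

    q_cur = subject.comfort_posture
    sh_cur = geometry.shoulder_home.copy()
    ik_cache: dict = {}
    rows_q, rows_sh, rows_in, rows_trial = [], [], [], []
    outcomes: list[TrialOutcome] = []
    t_offset = 0

    for trial_id, target in enumerate(order.sequence):
        q_traj, sh_traj, q_goal = natural_reach(
            q_cur, sh_cur, target, subject, geometry, rng, _cache=ik_cache
        )
        mon = TrialMonitor(hold_s, timeout_s)
        flags_all = []
        i = 0
        while not mon.done:
            if i >= len(q_traj):
                # keep dwelling (with fresh noise) until success or timeout
                n_ext = int(round(1.0 / DT))
                ext_q = np.tile(q_goal.as_array(), (n_ext, 1))
                noise = _smooth_noise(rng, n_ext, subject.motor_noise_sd, 7)
                lim = limits_array()
                ext_q = np.clip(ext_q + noise, lim[:, 0], lim[:, 1])
                q_traj = np.vstack([q_traj, ext_q])
                sh_traj = np.vstack([sh_traj, np.tile(sh_traj[-1], (n_ext, 1))])
            f = fk_batch(q_traj[i], geometry, sh_traj[i])
            fz = bool(
                in_zone_batch(f["hand_center"], f["axis"], target, tol)[0]
            )
            flags_all.append(fz)
            mon.update(fz)
            i += 1
        end = mon.end_index
        start_f = fk_batch(q_traj[0], geometry, sh_traj[0])
        outcome = mon.outcome(
            trial_id,
            target,
            HandPose(start_f["hand_center"][0], start_f["axis"][0]),
        )
        outcomes.append(outcome)
        n_keep = end + 1
        rows_q.append(q_traj[:n_keep])
        rows_sh.append(sh_traj[:n_keep])
        rows_in.append(np.array(flags_all[:n_keep], dtype=bool))
        rows_trial.append(np.full(n_keep, trial_id))
        q_cur = JointPosture.from_array(q_traj[n_keep - 1])
        sh_cur = sh_traj[n_keep - 1]
        t_offset += n_keep

    q_all = np.vstack(rows_q)
    sh_all = np.vstack(rows_sh)
    n = len(q_all)
    df = pd.DataFrame(q_all, columns=ANGLE_COLS)
    df.insert(0, "trial_id", np.concatenate(rows_trial))
    df.insert(0, "phase", phase)
    df.insert(0, "t", np.arange(n) * DT)
    df[["shx", "shy", "shz"]] = sh_all
    df["in_zone"] = np.concatenate(rows_in)
    rec = MotionRecording(
        df=df,
        trials=outcomes,
        phase=phase,
        meta={"subject_seed": subject.seed, "order_seed": order.seed,
              "tolerance": [tol.spatial, tol.angular],
              "subject_params": _subject_meta(subject)},
    )
    return rec, outcomes


@dataclass
class UserModelState:
    """Closed-loop user state during hybrid control."""

    q_sh: np.ndarray  # commanded shoulder angles (3,), deg
    trunk_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    err_trace: list = field(default_factory=list)
    e0: float | None = None  # error at trial start
    trunk_frozen: bool = False


def _predict_distal(predictor, q_sh_batch, sh_pos, target):
    """Predictor inputs for a batch of shoulder-angle rows."""
    if getattr(predictor, "mode", "C-") == "C+":
        ctx = np.concatenate([target.position - sh_pos, [target.tilt]])
        x = np.hstack([q_sh_batch, np.tile(ctx, (len(q_sh_batch), 1))])
    else:
        x = q_sh_batch
    return predictor.predict(x)


def hybrid_step(
    state: UserModelState,
    predictor,
    target: Target,
    subject: SubjectParams,
    geometry: ArmGeometry,
    shoulder_base: np.ndarray,
    q_sh_natural: np.ndarray | None = None,
    in_zone_prev: bool = False,
    gain: float = 0.05,
    ff_gain: float = 0.018,
    fd_step_deg: float = 0.5,
    axis_weight: float = 0.2,
    max_step_deg: float = 0.8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Advance the user model one sample.

    Returns (displayed 7-angle posture, shoulder position, pose error).
    The shoulder command combines a feedforward pull toward the subject's
    natural shoulder posture for this target (the coordination the subject
    would use with an intact arm) with a damped least-squares feedback
    step on the 6-D pose error computed through the composite
    shoulder→(shoulder, predicted distal)→FK map (Jacobian by forward
    differences). Compensatory trunk translation engages at ``trunk_gain``
    per unit normalized residual only while the shoulder-only error has
    plateaued outside the target zone, and relaxes back toward the
    backrest while the hand is held in the zone.
    """
    lim = limits_array()
    sh_pos = shoulder_base + state.trunk_offset
    # batch: nominal + 3 shoulder perturbations
    q_batch = np.tile(state.q_sh, (4, 1))
    for k in range(3):
        q_batch[k + 1, k] += fd_step_deg
    distal = _predict_distal(predictor, q_batch, sh_pos, target)
    q_full = np.hstack([q_batch, distal])
    q_full = np.clip(q_full, lim[:, 0], lim[:, 1])
    f = fk_batch(q_full, geometry, sh_pos)
    goal_c, goal_a = target.position, target.axis

    def err_vec(i):
        a = f["axis"][i]
        ga = goal_a if a @ goal_a >= 0 else -goal_a
        e_ax = (ga - (a @ ga) * a) * axis_weight
        return np.concatenate([goal_c - f["hand_center"][i], e_ax])

    e0 = err_vec(0)
    res = float(np.linalg.norm(e0))
    jac = np.zeros((6, 3))
    h = np.deg2rad(fd_step_deg)
    for k in range(3):
        jac[:, k] = -(err_vec(k + 1) - e0) / h  # d(attained)/dq = -d(err)/dq
    jjt = jac @ jac.T + 0.05**2 * np.eye(6)
    dq = jac.T @ np.linalg.solve(jjt, e0)
    step = np.rad2deg(gain * dq)
    if q_sh_natural is not None:
        step = step + ff_gain * (np.asarray(q_sh_natural) - state.q_sh)
    step = np.clip(step, -max_step_deg, max_step_deg)
    state.q_sh = np.clip(state.q_sh + step, lim[:3, 0], lim[:3, 1])

    # compensatory trunk translation
    if state.e0 is None:
        state.e0 = res
    state.err_trace.append(res)
    window = int(round(0.5 / DT))
    if state.e0 > 0 and res > 10 * state.e0:
        state.trunk_frozen = True
    plateaued = (
        len(state.err_trace) > window
        and state.err_trace[-window - 1] - res
        < 0.01 * max(state.err_trace[-window - 1], 1e-9)
    )
    if in_zone_prev:
        # discouraged-but-permitted compensation: ease back to the backrest
        state.trunk_offset = state.trunk_offset * 0.995
    elif not state.trunk_frozen and plateaued:
        p_err = e0[:3]
        nrm = np.linalg.norm(p_err)
        if nrm > 1e-9:
            r = min(1.0, res / max(state.e0, 1e-9))
            state.trunk_offset = state.trunk_offset + (
                subject.trunk_gain * r * p_err / nrm
            )
            tn = np.linalg.norm(state.trunk_offset)
            if tn > subject.max_trunk_offset:
                state.trunk_offset *= subject.max_trunk_offset / tn
    return q_full[0], sh_pos, res


def _mimic_distal_step(
    q_sh: np.ndarray,
    mim_distal: np.ndarray,
    target: Target,
    subject: SubjectParams,
    geometry: ArmGeometry,
    sh_pos: np.ndarray,
    iters: int = 1,
    axis_weight: float = 0.2,
) -> np.ndarray:
    """Track the natural distal solution for the commanded shoulder angles.

    A warm-started DLS iteration restricted to the four distal DoFs,
    with the comfort-bias attractor in the null space: what the subject's
    real (invisible) forearm would plausibly have done. One iteration per
    90 Hz sample tracks the slowly-moving solution closely.
    """
    lim = limits_array()
    comfort = subject.comfort_posture.as_array()[3:] + distal_bias(
        target, subject, geometry
    )
    q = np.concatenate([q_sh, mim_distal])
    for _ in range(iters):
        jac, f = _jacobian(q, geometry, sh_pos, axis_weight)
        e, _, _ = _pose_error(f, target.position, target.axis, axis_weight)
        jd = jac[:, 3:]
        jjt = jd @ jd.T + 0.05**2 * np.eye(6)
        dq = jd.T @ np.linalg.solve(jjt, e)
        pinv = jd.T @ np.linalg.solve(jjt, jd)
        grad = np.deg2rad(q[3:] - comfort)
        dq_null = -(np.eye(4) - pinv) @ grad * 0.1
        q[3:] = np.clip(
            q[3:] + np.rad2deg(0.5 * dq + dq_null), lim[3:, 0], lim[3:, 1]
        )
    return q[3:]


def simulate_phase_hybrid(
    order: TargetOrder,
    predictor,
    tol: Tolerance,
    subject: SubjectParams,
    geometry: ArmGeometry,
    rng: np.random.Generator,
    phase: str = "testC+",
    hold_s: float = 1.0,
    timeout_s: float = 15.0,
) -> tuple[MotionRecording, list[TrialOutcome]]:
    """Run a hybrid-control phase: displayed + mimicked posture streams.

    The two streams share the commanded shoulder angles sample by sample;
    the displayed stream's distal angles come from the predictor, the
    mimicked stream's from the natural distal tracker.
    """
    import pandas as pd

    comfort = subject.comfort_posture.as_array()
    state = UserModelState(q_sh=comfort[:3].copy())
    mim_distal = comfort[3:].copy()
    prev_nat = np.zeros(3)
    ik_cache: dict = {}

    rows_q, rows_sh, rows_in, rows_trial, rows_mim = [], [], [], [], []
    outcomes: list[TrialOutcome] = []
    ramp_n = int(round(0.4 / DT))

    for trial_id, target in enumerate(order.sequence):
        nat_off = natural_shoulder_offset(target, subject, geometry)
        q_nat_sh = goal_posture(target, subject, geometry, _cache=ik_cache)[0].as_array()[:3]
        mon = TrialMonitor(hold_s, timeout_s)
        state.e0 = None
        state.err_trace = []
        state.trunk_frozen = False
        i = 0
        start_pose = None
        in_zone_prev = False
        while not mon.done:
            w = min(1.0, i / ramp_n)
            shoulder_base = geometry.shoulder_home + (
                (1 - w) * prev_nat + w * nat_off
            )
            q_disp, sh_pos, _ = hybrid_step(
                state, predictor, target, subject, geometry, shoulder_base,
                q_sh_natural=q_nat_sh, in_zone_prev=in_zone_prev,
            )
            noise = rng.normal(0.0, 0.3 * subject.motor_noise_sd, 3)
            q_disp = q_disp.copy()
            q_disp[:3] = np.clip(
                q_disp[:3] + noise,
                limits_array()[:3, 0],
                limits_array()[:3, 1],
            )
            mim_distal = _mimic_distal_step(
                q_disp[:3], mim_distal, target, subject, geometry, sh_pos
            )
            f = fk_batch(q_disp, geometry, sh_pos)
            if start_pose is None:
                start_pose = HandPose(f["hand_center"][0], f["axis"][0])
            fz = bool(in_zone_batch(f["hand_center"], f["axis"], target, tol)[0])
            rows_q.append(q_disp)
            rows_sh.append(sh_pos)
            rows_in.append(fz)
            rows_trial.append(trial_id)
            rows_mim.append(np.concatenate([q_disp[:3], mim_distal]))
            mon.update(fz)
            in_zone_prev = fz
            i += 1
        outcomes.append(mon.outcome(trial_id, target, start_pose))
        prev_nat = nat_off

    q_all = np.array(rows_q)
    n = len(q_all)
    df = pd.DataFrame(q_all, columns=ANGLE_COLS)
    df.insert(0, "trial_id", np.array(rows_trial))
    df.insert(0, "phase", phase)
    df.insert(0, "t", np.arange(n) * DT)
    df[["shx", "shy", "shz"]] = np.array(rows_sh)
    df["in_zone"] = np.array(rows_in)
    df[MIM_COLS] = np.array(rows_mim)
    rec = MotionRecording(
        df=df,
        trials=outcomes,
        phase=phase,
        meta={"subject_seed": subject.seed, "order_seed": order.seed,
              "tolerance": [tol.spatial, tol.angular],
              "predictor_mode": getattr(predictor, "mode", "?"),
              "subject_params": _subject_meta(subject)},
    )
    return rec, outcomes
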
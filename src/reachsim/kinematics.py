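"""Geometric model of a three-segment, seven-DoF arm.

The arm has three rigid segments (upper arm, forearm, hand) linked by
spherical joints, of which seven rotational degrees of freedom are used:
three at the shoulder (flexion-extension, abduction-adduction, humeral
rotation), elbow flexion, forearm pronation-supination, and two at the
wrist (radial-ulnar deviation, flexion-extension).

Conventions
-----------
World frame: right-handed, ``x`` anterior (subject faces +x), ``y`` to the
subject's left, ``z`` up.

Neutral posture (all seven angles zero): arm hanging at the side, palm
facing medially; every segment frame coincides with the world frame and
each segment extends along local ``-z``.

Rotation composition (intrinsic, all matrices world-from-segment)::

    R_upper = Ry(-sh_flex) @ Rx(sh_abd) @ Rz(hum_rot)
    R_fore  = R_upper @ Ry(-el_flex) @ Rz(for_sup)
    R_hand  = R_fore  @ Ry(-wr_ext)  @ Rx(wr_dev)

so positive shoulder/elbow/wrist flexion rotates the limb anteriorly,
positive abduction moves it toward +y, and axial rotations are about the
segment's long axis. The Euler singularity sits at |sh_abd| = 90°, at the
edge of the anatomical workspace. The grasp axis is the hand-frame vector
that is world-vertical in the neutral posture (local ``+z``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOF_NAMES = ("sh_flex", "sh_abd", "hum_rot", "el_flex", "for_sup", "wr_dev", "wr_ext")

#: Standard anatomical ranges of motion, degrees.
DEFAULT_JOINT_LIMITS: dict[str, tuple[float, float]] = {
    "sh_flex": (-60.0, 170.0),
    "sh_abd": (-30.0, 120.0),
    "hum_rot": (-90.0, 90.0),
    "el_flex": (0.0, 150.0),
    "for_sup": (-85.0, 85.0),
    "wr_dev": (-30.0, 20.0),
    "wr_ext": (-85.0, 85.0),
}


def limits_array(limits: dict[str, tuple[float, float]] | None = None) -> np.ndarray:
    """Joint limits as a (7, 2) array ordered like :data:`DOF_NAMES`."""
    limits = limits or DEFAULT_JOINT_LIMITS
    return np.array([limits[n] for n in DOF_NAMES], dtype=float)


class JointLimitError(ValueError):
    """A joint angle lies outside its configured anatomical range."""


class UnreachableGoalError(ValueError):
    """The requested hand pose lies beyond the arm's reach radius."""


class IKConvergenceError(RuntimeError):
    """The IK solver exhausted its iteration budget.

    Carries ``best_residual`` = (position error m, axis error deg) of the
    best posture found.
    """

    def __init__(self, message: str, best_residual: tuple[float, float]):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths (m) and the resting shoulder-center position."""

    upper_arm_length: float = 0.30
    forearm_length: float = 0.25
    hand_length: float = 0.08
    shoulder_home: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0])
    )

    def __post_init__(self):
        if min(self.upper_arm_length, self.forearm_length, self.hand_length) <= 0:
            raise ValueError("segment lengths must be strictly positive")
        object.__setattr__(
            self, "shoulder_home", np.asarray(self.shoulder_home, dtype=float)
        )

    @property
    def total_reach(self) -> float:
        return self.upper_arm_length + self.forearm_length + self.hand_length


@dataclass(frozen=True)
class JointPosture:
    """The seven joint angles, degrees."""

    sh_flex: float
    sh_abd: float
    hum_rot: float
    el_flex: float
    for_sup: float
    wr_dev: float
    wr_ext: float

    @classmethod
    def from_array(cls, q: np.ndarray) -> "JointPosture":
        q = np.asarray(q, dtype=float)
        if q.shape != (7,):
            raise ValueError("posture array must have exactly 7 angles")
        return cls(*q.tolist())

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, n) for n in DOF_NAMES], dtype=float
        )

    @classmethod
    def neutral(cls) -> "JointPosture":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SegmentFrames:
    """World-frame orientations (rotation matrices) and joint-center positions."""

    r_upper: np.ndarray
    r_fore: np.ndarray
    r_hand: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray
    hand_center: np.ndarray


@dataclass(frozen=True)
class HandPose:
    """Hand center (m) and unit grasp axis."""

    center: np.ndarray
    axis: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if abs(n - 1.0) > 1e-9:
            a = a / n
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "axis", a)


def check_limits(q: np.ndarray, limits: np.ndarray | None = None) -> None:
    """Raise :class:`JointLimitError` naming the first out-of-range DoF."""
    lim = limits if limits is not None else limits_array()
    q = np.asarray(q, dtype=float)
    bad = (q < lim[:, 0] - 1e-9) | (q > lim[:, 1] + 1e-9)
    if bad.any():
        i = int(np.argmax(bad))
        raise JointLimitError(
            f"{DOF_NAMES[i]} = {q[i]:.3f} deg outside limits "
            f"[{lim[i, 0]}, {lim[i, 1]}]"
        )


# -- batched rotation primitives ------------------------------------------

def _rx(t):
    t = np.asarray(t, dtype=float)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros(t.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def _ry(t):
    t = np.asarray(t, dtype=float)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros(t.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _rz(t):
    t = np.asarray(t, dtype=float)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros(t.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def fk_batch(
    q_deg: np.ndarray,
    geometry: ArmGeometry,
    shoulder_position: np.ndarray,
):
    """Vectorized forward kinematics.

    Parameters
    ----------
    q_deg
        (n, 7) joint angles in degrees (a single (7,) vector is promoted).
    shoulder_position
        (3,) or (n, 3) shoulder-center position(s) in the world frame.

    Returns
    -------
    dict with (n, 3, 3) rotations ``r_upper/r_fore/r_hand``, (n, 3)
    positions ``elbow/wrist/hand_center`` and (n, 3) unit ``axis``.
    """
    q = np.atleast_2d(np.asarray(q_deg, dtype=float))
    qr = np.deg2rad(q)
    sh = np.broadcast_to(
        np.asarray(shoulder_position, dtype=float), (q.shape[0], 3)
    )

    r_upper = _ry(-qr[:, 0]) @ _rx(qr[:, 1]) @ _rz(qr[:, 2])
    r_fore = r_upper @ _ry(-qr[:, 3]) @ _rz(qr[:, 4])
    r_hand = r_fore @ _ry(-qr[:, 6]) @ _rx(qr[:, 5])

    down = np.array([0.0, 0.0, -1.0])
    elbow = sh + geometry.upper_arm_length * (r_upper @ down)
    wrist = elbow + geometry.forearm_length * (r_fore @ down)
    hand = wrist + geometry.hand_length * (r_hand @ down)
    axis = r_hand @ np.array([0.0, 0.0, 1.0])
    return {
        "r_upper": r_upper,
        "r_fore": r_fore,
        "r_hand": r_hand,
        "elbow": elbow,
        "wrist": wrist,
        "hand_center": hand,
        "axis": axis,
    }


def forward_kinematics(
    posture: JointPosture | np.ndarray,
    geometry: ArmGeometry,
    shoulder_position: np.ndarray | None = None,
    limits: np.ndarray | None = None,
    check: bool = True,
) -> tuple[SegmentFrames, HandPose]:
    """Hand pose and segment frames for one posture.

    Raises :class:`JointLimitError` if ``check`` and the posture violates
    the configured limits.
    """
    q = posture.as_array() if isinstance(posture, JointPosture) else np.asarray(posture, float)
    if check:
        check_limits(q, limits)
    sh = geometry.shoulder_home if shoulder_position is None else shoulder_position
    f = fk_batch(q, geometry, sh)
    frames = SegmentFrames(
        r_upper=f["r_upper"][0],
        r_fore=f["r_fore"][0],
        r_hand=f["r_hand"][0],
        elbow=f["elbow"][0],
        wrist=f["wrist"][0],
        hand_center=f["hand_center"][0],
    )
    return frames, HandPose(center=f["hand_center"][0], axis=f["axis"][0])


def angles_from_segment_orientations(frames: SegmentFrames) -> JointPosture:
    """Recover the seven joint angles from recorded segment orientations.

    Inverts the declared intrinsic Euler factorizations. At the
    |sh_abd| = 90° gimbal singularity only sh_flex ∓ hum_rot is defined;
    the tie-break sets hum_rot = 0 and absorbs the remainder into sh_flex
    (staying on the |sh_abd| ≤ 90° anatomical branch).
    """
    ru = np.asarray(frames.r_upper, dtype=float)
    # R_upper = Ry(a) Rx(b) Rz(g), a = -sh_flex, b = sh_abd, g = hum_rot
    sb = np.clip(-ru[1, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(abs(sb) - 1.0) < 1e-12:
        g = 0.0
        if sb > 0:  # row0 = [cos(a-g), sin(a-g), 0]
            a = np.arctan2(ru[0, 1], ru[0, 0])
        else:  # row0 = [cos(a+g), -sin(a+g), 0]
            a = np.arctan2(-ru[0, 1], ru[0, 0])
    else:
        a = np.arctan2(ru[0, 2], ru[2, 2])
        g = np.arctan2(ru[1, 0], ru[1, 1])

    # elbow + forearm: R_upper^T R_fore = Ry(-el_flex) Rz(for_sup)
    rel = ru.T @ np.asarray(frames.r_fore, dtype=float)
    el = -np.arctan2(rel[0, 2], rel[2, 2])
    sup = np.arctan2(rel[1, 0], rel[1, 1])

    # wrist: R_fore^T R_hand = Ry(-wr_ext) Rx(wr_dev)
    rw = np.asarray(frames.r_fore, dtype=float).T @ np.asarray(frames.r_hand, dtype=float)
    ext = np.arctan2(rw[2, 0], rw[0, 0])
    dev = np.arctan2(-rw[1, 2], rw[1, 1])

    return JointPosture.from_array(
        np.rad2deg(np.array([-a, b, g, el, sup, dev, ext]))
    )


def axis_from_tilt(tilt_deg: float) -> np.ndarray:
    """Unit target axis: world vertical rotated by ``tilt`` in the frontal plane.

    Positive tilt is counterclockwise as seen by the subject, i.e. the top
    of the axis moves toward the subject's left (+y).
    """
    if not -90.0 <= tilt_deg <= 90.0:
        raise ValueError("tilt must lie in [-90, 90] degrees")
    t = np.deg2rad(tilt_deg)
    return np.array([0.0, np.sin(t), np.cos(t)])


def _pose_error(f, goal_center, goal_axis, axis_weight):
    """Stacked 6-vector error: [goal − hand center; weighted desired δaxis].

    The axis block is the component of the (sign-matched) goal axis
    orthogonal to the current axis, with norm sin(misalignment angle).
    """
    p_err = goal_center - f["hand_center"][0]
    a = f["axis"][0]
    ga = goal_axis if a @ goal_axis >= 0 else -goal_axis  # unsigned axis
    e_ax = (ga - (a @ ga) * a) * axis_weight
    return np.concatenate([p_err, e_ax]), p_err, ga


def _cross3(a, b):
    """3-vector cross product without np.cross's axis-handling overhead."""
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _jacobian(q_deg, geometry, shoulder_position, axis_weight):
    """Analytic geometric Jacobian [d hand_center/dq; d axis/dq], per radian."""
    f = fk_batch(q_deg, geometry, shoulder_position)
    ru, rf = f["r_upper"][0], f["r_fore"][0]
    p_el, p_wr, p_h = f["elbow"][0], f["wrist"][0], f["hand_center"][0]
    sh = np.broadcast_to(np.asarray(shoulder_position, dtype=float), (3,))
    a = f["axis"][0]
    qr = np.deg2rad(np.asarray(q_deg, float).reshape(7))

    y, x, z = np.eye(3)[1], np.eye(3)[0], np.eye(3)[2]
    r1 = _ry(-qr[0])
    r12 = r1 @ _rx(qr[1])
    r_el = ru @ _ry(-qr[3])
    r_we = rf @ _ry(-qr[6])
    # world-frame joint rotation axes and the joint centers they act through
    axes = [
        (-y, sh),                 # sh_flex about -y
        (r1 @ x, sh),             # sh_abd
        (r12 @ z, sh),            # hum_rot
        (ru @ -y, p_el),          # el_flex
        (r_el @ z, p_el),         # for_sup
        (r_we @ x, p_wr),         # wr_dev
        (rf @ -y, p_wr),          # wr_ext
    ]
    jac = np.zeros((6, 7))
    for i, (w, c) in enumerate(axes):
        jac[:3, i] = _cross3(w, p_h - c)
        jac[3:, i] = _cross3(w, a) * axis_weight
    return jac, f


def solve_ik(
    goal: HandPose,
    geometry: ArmGeometry,
    shoulder_position: np.ndarray,
    init: JointPosture,
    posture_cost_weights: np.ndarray | None = None,
    comfort_posture: JointPosture | None = None,
    tol_position: float = 1e-3,
    tol_axis_deg: float = 0.5,
    damping: float = 0.05,
    max_iter: int = 500,
    null_gain: float = 0.1,
    limits: np.ndarray | None = None,
    n_restarts: int = 50,
    dof_scales: np.ndarray | None = None,
) -> JointPosture:
    """Damped-least-squares IK with null-space descent on a posture cost.

    The returned posture reproduces ``goal`` within the tolerances while
    locally minimizing the weighted squared deviation from
    ``comfort_posture`` in the pose null space. Deterministic for fixed
    inputs; a few deterministic perturbed restarts guard against joint-limit
    dead ends.

    Raises
    ------
    UnreachableGoalError
        if the goal center lies beyond the total reach radius.
    IKConvergenceError
        if no tolerance-satisfying posture is found.
    """
    sh = np.asarray(shoulder_position, dtype=float)
    goal_center = np.asarray(goal.center, dtype=float)
    goal_axis = np.asarray(goal.axis, dtype=float)
    if np.linalg.norm(goal_center - sh) > geometry.total_reach:
        raise UnreachableGoalError(
            f"goal at {np.linalg.norm(goal_center - sh):.3f} m exceeds reach "
            f"radius {geometry.total_reach:.3f} m"
        )
    lim = limits if limits is not None else limits_array()
    w = (
        np.ones(7)
        if posture_cost_weights is None
        else np.asarray(posture_cost_weights, dtype=float)
    )
    q_comfort = (comfort_posture or init).as_array()
    axis_weight = 0.2  # m per rad: balances position and axis errors
    tol_ax = np.sin(np.deg2rad(tol_axis_deg)) * axis_weight

    best = (np.inf, init.as_array())
    q0 = init.as_array()
    # deterministic restarts: the caller's init, then a fixed spread of
    # in-limit postures covering the workspace (keeps the solver a pure
    # function of its inputs while escaping joint-limit dead ends)
    span = lim[:, 1] - lim[:, 0]
    restart_rng = np.random.default_rng(12345)
    inits = [q0] + [
        lim[:, 0] + span * restart_rng.uniform(0.05, 0.95, 7)
        for _ in range(max(0, n_restarts - 1))
    ]
    for q_init in inits:
        q = np.clip(q_init, lim[:, 0], lim[:, 1])
        stall = 0
        prev_res = np.inf
        for _ in range(max_iter):
            jac, f = _jacobian(q, geometry, sh, axis_weight)
            e, p_err, _ = _pose_error(f, goal_center, goal_axis, axis_weight)
            res = np.linalg.norm(e)
            if res < best[0]:
                best = (res, q.copy())
            if np.linalg.norm(p_err) <= tol_position and np.linalg.norm(e[3:]) <= tol_ax:
                return JointPosture.from_array(q)
            if res > prev_res * 0.999:
                stall += 1
                if stall > 10:
                    break  # dead-ended; try next restart
            else:
                stall = 0
            prev_res = res
            # damping annealed with the residual: near the solution the step
            # approaches Gauss-Newton and the damping bias vanishes
            lam = max(1e-4, min(damping, res))
            # optional per-DoF step scaling (reluctant DoFs get small
            # scales: the solver recruits them only when others cannot
            # reduce the error), then gradient projection at the joint
            # limits: saturated joints whose step points further out are
            # removed from the task Jacobian, so the remaining DoFs take
            # over instead of stalling at the wall
            jac_a = jac if dof_scales is None else jac * dof_scales[None, :]
            for _pass in range(7):
                jjt = jac_a @ jac_a.T + lam**2 * np.eye(6)
                dq = jac_a.T @ np.linalg.solve(jjt, e)
                if dof_scales is not None:
                    dq = dq * dof_scales
                sat = ((q <= lim[:, 0] + 1e-9) & (dq < 0)) | (
                    (q >= lim[:, 1] - 1e-9) & (dq > 0)
                )
                if not sat.any():
                    break
                jac_a = jac_a.copy()
                jac_a[:, sat] = 0.0
                dq[sat] = 0.0
            # null-space pull toward the comfort posture, annealed likewise so
            # it cannot hold the residual above tolerance
            pinv = jac_a.T @ np.linalg.solve(jjt, jac_a)
            grad = np.deg2rad(q - q_comfort) * w
            dq_null = -(np.eye(7) - pinv) @ grad * null_gain * min(
                1.0, res / (10 * tol_position)
            )
            # the comfort pull must never dominate the task step, or the
            # two can limit-cycle just outside tolerance
            cap = max(0.5 * np.linalg.norm(dq), 1e-3)
            nn = np.linalg.norm(dq_null)
            if nn > cap:
                dq_null *= cap / nn
            q = np.clip(q + np.rad2deg(dq + dq_null), lim[:, 0], lim[:, 1])
    res, q = best
    f = fk_batch(q, geometry, sh)
    p_err = np.linalg.norm(goal_center - f["hand_center"][0])
    cosang = abs(np.clip(f["axis"][0] @ goal_axis, -1, 1))
    raise IKConvergenceError(
        f"IK did not converge (position error {p_err * 1e3:.2f} mm)",
        best_residual=(float(p_err), float(np.rad2deg(np.arccos(cosang)))),
    )
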
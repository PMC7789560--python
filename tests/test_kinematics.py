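"""Forward/inverse kinematics and angle extraction."""

import numpy as np
import pytest

from reachsim.kinematics import (
    ArmGeometry,
    HandPose,
    IKConvergenceError,
    JointLimitError,
    JointPosture,
    UnreachableGoalError,
    angles_from_segment_orientations,
    axis_from_tilt,
    fk_batch,
    forward_kinematics,
    limits_array,
    solve_ik,
)


def _homogeneous_fk_oracle(q_deg, geometry):
    """Independent FK oracle: explicit 4x4 homogeneous transforms composed
    matrix by matrix."""

    def rot(axis, deg):
        t = np.deg2rad(deg)
        c, s = np.cos(t), np.sin(t)
        m = np.eye(4)
        if axis == "x":
            m[1:3, 1:3] = [[c, -s], [s, c]]
        elif axis == "y":
            m[0, 0], m[0, 2], m[2, 0], m[2, 2] = c, s, -s, c
        else:
            m[0:2, 0:2] = [[c, -s], [s, c]]
        return m

    def trans(v):
        m = np.eye(4)
        m[:3, 3] = v
        return m

    f, a, r, el, sup, dev, ext = q_deg
    lu, lf, lh = (
        geometry.upper_arm_length,
        geometry.forearm_length,
        geometry.hand_length,
    )
    t = rot("y", -f) @ rot("x", a) @ rot("z", r) @ trans([0, 0, -lu])
    elbow = t[:3, 3]
    t = t @ rot("y", -el) @ rot("z", sup) @ trans([0, 0, -lf])
    wrist = t[:3, 3]
    t = t @ rot("y", -ext) @ rot("x", dev) @ trans([0, 0, -lh])
    hand = t[:3, 3]
    axis = t[:3, :3] @ [0, 0, 1]
    return elbow, wrist, hand, axis


def test_neutral_posture_identity(geometry):
    """Arm hanging at the side: hand straight below the shoulder, grasp
    axis vertical."""
    frames, pose = forward_kinematics(JointPosture.neutral(), geometry)
    np.testing.assert_allclose(
        pose.center, [0, 0, -geometry.total_reach], atol=1e-12
    )
    np.testing.assert_allclose(pose.axis, [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(frames.r_upper, np.eye(3), atol=1e-12)


def test_elbow_flexion_moves_hand_forward(geometry):
    """90° elbow flexion leaves the elbow in place and sends the distal
    chain horizontally forward."""
    frames, pose = forward_kinematics(JointPosture(0, 0, 0, 90, 0, 0, 0), geometry)
    np.testing.assert_allclose(
        frames.elbow, [0, 0, -geometry.upper_arm_length], atol=1e-12
    )
    np.testing.assert_allclose(
        pose.center,
        [
            geometry.forearm_length + geometry.hand_length,
            0,
            -geometry.upper_arm_length,
        ],
        atol=1e-12,
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fk_matches_homogeneous_transform_oracle(geometry, seed):
    rng = np.random.default_rng(seed)
    lim = limits_array()
    for _ in range(50):
        q = rng.uniform(lim[:, 0], lim[:, 1])
        frames, pose = forward_kinematics(q, geometry)
        elbow, wrist, hand, axis = _homogeneous_fk_oracle(q, geometry)
        np.testing.assert_allclose(frames.elbow, elbow, atol=1e-9)
        np.testing.assert_allclose(frames.wrist, wrist, atol=1e-9)
        np.testing.assert_allclose(pose.center, hand, atol=1e-9)
        np.testing.assert_allclose(pose.axis, axis, atol=1e-9)


def test_fk_preserves_segment_lengths(geometry):
    rng = np.random.default_rng(3)
    lim = limits_array()
    q = rng.uniform(lim[:, 0], lim[:, 1], size=(500, 7))
    f = fk_batch(q, geometry, geometry.shoulder_home)
    d1 = np.linalg.norm(f["elbow"] - geometry.shoulder_home, axis=1)
    d2 = np.linalg.norm(f["wrist"] - f["elbow"], axis=1)
    d3 = np.linalg.norm(f["hand_center"] - f["wrist"], axis=1)
    np.testing.assert_allclose(d1, geometry.upper_arm_length, atol=1e-12)
    np.testing.assert_allclose(d2, geometry.forearm_length, atol=1e-12)
    np.testing.assert_allclose(d3, geometry.hand_length, atol=1e-12)


def test_hand_within_reach_radius(geometry):
    rng = np.random.default_rng(4)
    lim = limits_array()
    q = rng.uniform(lim[:, 0], lim[:, 1], size=(2000, 7))
    f = fk_batch(q, geometry, geometry.shoulder_home)
    d = np.linalg.norm(f["hand_center"] - geometry.shoulder_home, axis=1)
    assert (d <= geometry.total_reach + 1e-12).all()


def test_angle_extraction_round_trip(geometry):
    """FK then angle extraction is the identity on the non-singular branch
    (|sh_abd| < 90°), to well under 1e-6 degrees."""
    rng = np.random.default_rng(5)
    lim = limits_array().copy()
    lim[1] = [-30.0, 89.0]  # stay off the abduction singularity branch
    worst = 0.0
    for _ in range(10_000):
        q = rng.uniform(lim[:, 0], lim[:, 1])
        frames, _ = forward_kinematics(q, geometry, check=False)
        q2 = angles_from_segment_orientations(frames).as_array()
        worst = max(worst, np.abs(q - q2).max())
    assert worst < 1e-6


def test_angle_extraction_specific_vector(geometry):
    q = np.array([10.0, 20.0, -15.0, 45.0, 30.0, 5.0, -10.0])
    frames, _ = forward_kinematics(q, geometry)
    np.testing.assert_allclose(
        angles_from_segment_orientations(frames).as_array(), q, atol=1e-6
    )


def test_identity_frames_give_neutral_posture(geometry):
    frames, _ = forward_kinematics(JointPosture.neutral(), geometry)
    q = angles_from_segment_orientations(frames).as_array()
    np.testing.assert_allclose(q, np.zeros(7), atol=1e-9)


def test_gimbal_tie_break_stays_on_anatomical_branch(geometry):
    """At 90° abduction both Euler factorizations describe the same
    orientation; the extraction must return the documented one
    (hum_rot = 0, |sh_abd| <= 90) and reproduce the orientation."""
    q = np.array([25.0, 90.0, 40.0, 30.0, 10.0, 5.0, -5.0])
    frames, _ = forward_kinematics(q, geometry, check=False)
    q2 = angles_from_segment_orientations(frames).as_array()
    assert abs(q2[1]) <= 90.0 + 1e-9
    assert q2[2] == pytest.approx(0.0, abs=1e-9)
    frames2, _ = forward_kinematics(q2, geometry, check=False)
    np.testing.assert_allclose(frames2.r_upper, frames.r_upper, atol=1e-9)
    np.testing.assert_allclose(frames2.r_hand, frames.r_hand, atol=1e-9)


def test_out_of_limit_posture_names_the_dof(geometry):
    with pytest.raises(JointLimitError, match="el_flex"):
        forward_kinematics(JointPosture(0, 0, 0, 160, 0, 0, 0), geometry)


class TestAxisFromTilt:
    def test_zero_tilt_is_vertical(self):
        np.testing.assert_allclose(axis_from_tilt(0.0), [0, 0, 1], atol=1e-12)

    def test_ninety_points_left(self):
        np.testing.assert_allclose(axis_from_tilt(90.0), [0, 1, 0], atol=1e-12)

    def test_intermediate_tilt_components(self):
        v = axis_from_tilt(22.5)
        assert v[2] == pytest.approx(np.cos(np.deg2rad(22.5)))
        assert v[1] == pytest.approx(np.sin(np.deg2rad(22.5)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            axis_from_tilt(120.0)


class TestSolveIK:
    def test_comfort_goal_is_fixed_point(self, geometry, comfort):
        _, goal = forward_kinematics(comfort, geometry)
        q = solve_ik(
            goal, geometry, geometry.shoulder_home, init=comfort,
            comfort_posture=comfort,
        )
        _, pose = forward_kinematics(q, geometry)
        assert np.linalg.norm(pose.center - goal.center) <= 1e-3
        # fixed point: the solver should stay at (or return to) comfort
        np.testing.assert_allclose(q.as_array(), comfort.as_array(), atol=0.5)

    def test_beyond_reach_radius_is_unreachable(self, geometry, comfort):
        goal = HandPose(
            np.array([0, 0, -geometry.total_reach * 1.01]), np.array([0, 0, 1.0])
        )
        with pytest.raises(UnreachableGoalError):
            solve_ik(goal, geometry, geometry.shoulder_home, init=comfort)

    def test_closure_on_random_reachable_goals(self, geometry, comfort):
        """FK(solve_ik(goal)) within {1 mm, 0.5 deg} of goal on 200 random
        reachable goals (goals generated as FK of random in-limit
        postures)."""
        rng = np.random.default_rng(10)
        lim = limits_array()
        n_ok = 0
        for _ in range(200):
            q = rng.uniform(lim[:, 0] * 0.8, lim[:, 1] * 0.8)
            _, goal = forward_kinematics(q, geometry, check=False)
            sol = solve_ik(
                goal, geometry, geometry.shoulder_home, init=comfort,
                comfort_posture=comfort,
            )
            _, pose = forward_kinematics(sol, geometry)
            p_err = np.linalg.norm(pose.center - goal.center)
            ang = np.rad2deg(
                np.arccos(np.clip(abs(pose.axis @ goal.axis), -1, 1))
            )
            n_ok += p_err <= 1e-3 and ang <= 0.5
        assert n_ok == 200

    def test_deterministic(self, geometry, comfort):
        _, goal = forward_kinematics(
            JointPosture(30, 20, 0, 80, 0, 0, 0), geometry
        )
        a = solve_ik(goal, geometry, geometry.shoulder_home, init=comfort,
                     comfort_posture=comfort)
        b = solve_ik(goal, geometry, geometry.shoulder_home, init=comfort,
                     comfort_posture=comfort)
        assert a.as_array().tobytes() == b.as_array().tobytes()
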
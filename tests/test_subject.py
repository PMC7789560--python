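"""Synthetic subject: natural reaches, noise shaping, hybrid user model."""

import numpy as np
import pytest

from reachsim.kinematics import JointPosture, fk_batch
from reachsim.subject import (
    SubjectParams,
    UserModelState,
    distal_bias,
    goal_posture,
    hybrid_step,
    minimum_jerk,
    natural_reach,
    simulate_phase_natural,
)
from reachsim.tasks import (
    ACQUISITION_TOLERANCE,
    Target,
    Tolerance,
    generate_target_order,
    in_zone_batch,
)


def _two_tilt_targets(grid):
    idx = (2, 1, 0)
    return Target(idx, grid[idx], 0.0), Target(idx, grid[idx], 45.0)


class TestDistalBias:
    def test_coupling_zero_no_bias(self, grid, geometry):
        t0, t45 = _two_tilt_targets(grid)
        s = SubjectParams(context_coupling=0.0)
        assert np.allclose(distal_bias(t0, s, geometry), 0)
        assert np.allclose(distal_bias(t45, s, geometry), 0)

    def test_coupling_zero_identical_distal_goals(self, grid, geometry):
        """Same position, different tilts, coupling off: the distal goal
        differs only through the pose constraint, not the comfort bias."""
        t0, t45 = _two_tilt_targets(grid)
        s = SubjectParams(context_coupling=0.0, motor_noise_sd=0.0)
        b0 = distal_bias(t0, s, geometry)
        b45 = distal_bias(t45, s, geometry)
        np.testing.assert_array_equal(b0, b45)

    def test_bias_map_separates_tilts(self, grid, geometry):
        """The comfort-bias map itself differs substantially between two
        tilts at the same position (the configured redundancy magnitude)."""
        t0, t45 = _two_tilt_targets(grid)
        s1 = SubjectParams(context_coupling=1.0, motor_noise_sd=0.0)
        gap = np.linalg.norm(
            distal_bias(t45, s1, geometry) - distal_bias(t0, s1, geometry)
        )
        assert gap > 5.0

    def test_coupling_moves_distal_goal_not_shoulder(self, grid, geometry):
        """Turning the coupling on shifts the goal posture for a tilted
        target predominantly in the distal joints: redundancy that the
        shoulder angles cannot encode."""
        _, t45 = _two_tilt_targets(grid)
        s1 = SubjectParams(context_coupling=1.0, motor_noise_sd=0.0)
        s0 = SubjectParams(context_coupling=0.0, motor_noise_sd=0.0)
        q_c1 = goal_posture(t45, s1, geometry)[0].as_array()
        q_c0 = goal_posture(t45, s0, geometry)[0].as_array()
        distal_shift = np.linalg.norm(q_c1[3:] - q_c0[3:])
        shoulder_shift = np.linalg.norm(q_c1[:3] - q_c0[:3])
        assert distal_shift > 2.0
        assert distal_shift > shoulder_shift


class TestMinimumJerk:
    def test_endpoints_and_monotone(self):
        s = minimum_jerk(200)
        assert s[0] == 0.0 and s[-1] == pytest.approx(1.0)
        assert (np.diff(s) >= -1e-12).all()

    def test_velocity_peaks_mid_movement_and_vanishes_at_ends(self):
        s = minimum_jerk(1001)
        v = np.gradient(s)
        assert np.argmax(v) == 500
        assert v[0] == pytest.approx(0.0, abs=1e-4)
        assert v[-1] == pytest.approx(0.0, abs=1e-4)


class TestNaturalReach:
    def test_noise_free_terminal_sample_inside_acquisition_zone(
        self, grid, geometry, comfort
    ):
        t0, _ = _two_tilt_targets(grid)
        s = SubjectParams(context_coupling=1.0, motor_noise_sd=0.0)
        q, sh, _ = natural_reach(
            comfort, geometry.shoulder_home, t0, s, geometry,
            np.random.default_rng(0),
        )
        f = fk_batch(q[-1], geometry, sh[-1])
        tol = Tolerance(*ACQUISITION_TOLERANCE)
        assert in_zone_batch(f["hand_center"], f["axis"], t0, tol)[0]

    def test_duration_scales_with_distance(self, grid, geometry, comfort):
        s = SubjectParams(motor_noise_sd=0.0, movement_speed_gain=2.5)
        near = Target((2, 2, 0), grid[(2, 2, 0)], 0.0)
        q1, _, _ = natural_reach(
            comfort, geometry.shoulder_home, near, s, geometry,
            np.random.default_rng(0),
        )
        far = Target((4, 4, 1), grid[(4, 4, 1)], 0.0)
        q2, _, _ = natural_reach(
            comfort, geometry.shoulder_home, far, s, geometry,
            np.random.default_rng(0),
        )
        assert len(q1) > 0 and len(q2) > 0


class TestSimulatePhaseNatural:
    @pytest.fixture(scope="class")
    def phase(self, subset, geometry):
        order = generate_target_order(subset, 20, seed=5)
        order = type(order)(order.sequence[:20], order.seed)
        subject = SubjectParams(context_coupling=1.0, motor_noise_sd=0.0, seed=1)
        return simulate_phase_natural(
            order, Tolerance(*ACQUISITION_TOLERANCE), subject, geometry,
            np.random.default_rng(1),
        )

    def test_noise_free_success_rate_is_one(self, phase):
        _, outcomes = phase
        assert all(o.success for o in outcomes)

    def test_rows_bookkeeping(self, phase):
        rec, outcomes = phase
        expected = sum(round(o.end_time * 90) + 1 for o in outcomes)
        assert len(rec.df) == expected
        assert np.allclose(np.diff(rec.df["t"].to_numpy()), 1 / 90)

    def test_later_trials_have_positive_approach_time(self, phase):
        _, outcomes = phase
        assert all(o.approach_time > 0 for o in outcomes[1:])

    def test_deterministic_given_seeds(self, subset, geometry):
        order = generate_target_order(subset, 12, seed=6)
        order = type(order)(order.sequence[:12], order.seed)
        subject = SubjectParams(context_coupling=1.0, seed=2)
        a, _ = simulate_phase_natural(
            order, Tolerance(*ACQUISITION_TOLERANCE), subject, geometry,
            np.random.default_rng(2),
        )
        b, _ = simulate_phase_natural(
            order, Tolerance(*ACQUISITION_TOLERANCE), subject, geometry,
            np.random.default_rng(2),
        )
        assert a.df.equals(b.df)


class _OraclePredictor:
    """Stub returning the natural-reach distal goal for a fixed target."""

    mode = "C-"

    def __init__(self, target, subject, geometry):
        self.distal = goal_posture(target, subject, geometry)[0].as_array()[3:]

    def predict(self, x):
        return np.tile(self.distal, (np.atleast_2d(x).shape[0], 1))


class _ConstantPredictor:
    mode = "C-"

    def __init__(self, distal):
        self.distal = np.asarray(distal, float)

    def predict(self, x):
        return np.tile(self.distal, (np.atleast_2d(x).shape[0], 1))


class TestHybridStep:
    def test_oracle_predictor_converges_to_success(self, grid, geometry, comfort):
        """With a predictor that outputs the true natural distal angles,
        the user model completes the trial well inside the 15 s budget."""
        from reachsim.tasks import TEST_TOLERANCE, TrialMonitor

        t = Target((2, 1, 0), grid[(2, 1, 0)], 22.5)
        subject = SubjectParams(context_coupling=1.0, motor_noise_sd=0.0)
        pred = _OraclePredictor(t, subject, geometry)
        state = UserModelState(q_sh=comfort.as_array()[:3].copy())
        base = geometry.shoulder_home + np.zeros(3)
        mon = TrialMonitor()
        tol = Tolerance(*TEST_TOLERANCE)
        while not mon.done:
            q, sh, _ = hybrid_step(state, pred, t, subject, geometry, base)
            f = fk_batch(q, geometry, sh)
            mon.update(bool(in_zone_batch(f["hand_center"], f["axis"], t, tol)[0]))
        assert mon.success
        assert mon.end_index / 90.0 < 15.0

    def test_hopeless_predictor_times_out_with_trunk_compensation(
        self, grid, geometry, comfort
    ):
        from reachsim.tasks import TEST_TOLERANCE, TrialMonitor

        t = Target((2, 1, 0), grid[(2, 1, 0)], 0.0)
        subject = SubjectParams(context_coupling=1.0, motor_noise_sd=0.0)
        pred = _ConstantPredictor([0.0, -80.0, 15.0, -60.0])
        state = UserModelState(q_sh=comfort.as_array()[:3].copy())
        base = geometry.shoulder_home + np.zeros(3)
        mon = TrialMonitor()
        tol = Tolerance(*TEST_TOLERANCE)
        while not mon.done:
            q, sh, _ = hybrid_step(state, pred, t, subject, geometry, base)
            f = fk_batch(q, geometry, sh)
            mon.update(bool(in_zone_batch(f["hand_center"], f["axis"], t, tol)[0]))
        assert np.linalg.norm(state.trunk_offset) > 0.005
        assert np.linalg.norm(state.trunk_offset) <= subject.max_trunk_offset + 1e-9

    def test_mimicked_stream_shares_shoulder_angles(self, subset, geometry):
        """In a hybrid phase the displayed and mimicked streams carry
        identical shoulder angles at every sample."""
        from reachsim.recording import ANGLE_COLS, MIM_COLS
        from reachsim.subject import simulate_phase_hybrid
        from reachsim.tasks import TEST_TOLERANCE, generate_target_order

        order = generate_target_order(subset, 5, seed=31)
        order = type(order)(order.sequence[:5], order.seed)
        subject = SubjectParams(context_coupling=1.0, seed=4)
        pred = _OraclePredictor(order.sequence[0], subject, geometry)
        rec, outs = simulate_phase_hybrid(
            order, pred, Tolerance(0.04, 10.0), subject, geometry,
            np.random.default_rng(4),
        )
        np.testing.assert_array_equal(
            rec.df[ANGLE_COLS[:3]].to_numpy(), rec.df[MIM_COLS[:3]].to_numpy()
        )
        assert rec.mimicked_angles is not None

    def test_zero_error_is_fixed_point(self, grid, geometry):
        """If the displayed hand already sits exactly on the target, the
        shoulder command must not move."""
        t = Target((2, 1, 0), grid[(2, 1, 0)], 0.0)
        subject = SubjectParams(context_coupling=1.0, motor_noise_sd=0.0)
        q_goal, sh_goal = goal_posture(t, subject, geometry)
        pred = _ConstantPredictor(q_goal.as_array()[3:])
        state = UserModelState(q_sh=q_goal.as_array()[:3].copy())
        base = sh_goal
        q_before = state.q_sh.copy()
        hybrid_step(state, pred, t, subject, geometry, base)
        np.testing.assert_allclose(state.q_sh, q_before, atol=0.05)


class TestCouplingInformativeness:
    def test_rmse_gap_grows_with_context_coupling(self, geometry):
        """The offline penalty for ignoring context (RMSE C− minus RMSE
        C+) increases monotonically with the coupling strength; with the
        coupling off, the contextual inputs carry almost no extra
        information."""
        from reachsim.datasets import build_dataset
        from reachsim.predictors import Hyperparameters, offline_rmse, train
        from reachsim.tasks import (
            ACQUISITION_TOLERANCE,
            build_target_grid,
            build_target_set,
            generate_target_order,
        )

        grid = build_target_grid(geometry)
        whole = build_target_set(grid, "whole")
        order = generate_target_order(whole, 80, seed=8)
        order = type(order)(order.sequence[:80], order.seed)
        hyper = Hyperparameters(max_epochs=50, patience=10, max_train_rows=3500)
        gaps = []
        for c in (0.0, 0.5, 1.0):
            subject = SubjectParams(seed=5, context_coupling=c)
            rec, _ = simulate_phase_natural(
                order, Tolerance(*ACQUISITION_TOLERANCE), subject, geometry,
                np.random.default_rng(5),
            )
            rmse = {}
            for mode in ("C+", "C-"):
                ds = build_dataset(rec, mode)
                rmse[mode] = offline_rmse(train(ds, hyper, seed=3), ds).pooled
            gaps.append(rmse["C-"] - rmse["C+"])
        assert gaps[0] < gaps[1] < gaps[2]
        assert gaps[2] > 1.0  # full coupling leaves a substantial penalty
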
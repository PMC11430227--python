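"""Angular-interpolation controller: update laws, latching, state handling."""

import numpy as np
import pytest

import hybridarm as ha
from hybridarm.controller import (
    ControllerConfig,
    angular_update,
    angular_update_by_frequency,
    target_key,
)
from hybridarm.kinematics import DISTAL, PROXIMAL


@pytest.fixture
def scenario(oracle_setup, geometry, rom):
    """One target with its oracle predictor and a fresh controller state."""
    targets, postures, oracle = oracle_setup
    target, posture = targets[0], postures[0]
    start = 0.5 * (rom.min_deg + rom.max_deg)
    state = ha.initial_state(geometry, start, time=0.0, target=target)
    return target, posture, oracle, start, state


class TestGapAndSpeed:
    def test_gap_is_goal_minus_previous(self, geometry, rom):
        start = ha.joint_angles(efe=90)
        state = ha.initial_state(geometry, start)
        goal = start[DISTAL].copy()
        np.testing.assert_array_equal(ha.compute_gap(goal, state), np.zeros(5))
        goal[1] = 100.0  # efe gap of +10
        assert ha.compute_gap(goal, state)[1] == pytest.approx(10.0)
        goal[1] = 80.0
        assert ha.compute_gap(goal, state)[1] == pytest.approx(-10.0)

    def test_stationary_proximal_gives_zero_speed(self, geometry):
        start = ha.joint_angles(sfe=30, efe=90)
        state = ha.initial_state(geometry, start, time=0.0)
        assert ha.locked_hand_speed(geometry, start[PROXIMAL], state, 1 / 90) == 0.0

    def test_speed_is_displacement_over_elapsed_time(self, geometry):
        start = ha.joint_angles(sfe=30, efe=90)
        state = ha.initial_state(geometry, start, time=0.0)
        prox2 = start[PROXIMAL] + np.array([2.0, 0.0])
        locked = ha.locked_hand_position(geometry, prox2, start[DISTAL])
        expected = np.linalg.norm(locked - state.hand_prev) * 90.0
        assert ha.locked_hand_speed(geometry, prox2, state, 1 / 90) == pytest.approx(expected)

    def test_distal_only_motion_contributes_nothing(self, geometry):
        """Machine-driven distal motion must not feed back into the hand
        speed estimate (the locked-hand construction)."""
        start = ha.joint_angles(sfe=30, efe=90)
        state = ha.initial_state(geometry, start, time=0.0)
        # distal moved since t-1, proximal did not: the locked position is
        # computed with the *previous* distal, so the speed stays zero
        assert ha.locked_hand_speed(geometry, start[PROXIMAL], state, 1 / 90) == 0.0

    def test_time_must_increase(self, geometry):
        start = ha.joint_angles()
        state = ha.initial_state(geometry, start, time=1.0)
        with pytest.raises(ValueError):
            ha.locked_hand_speed(geometry, start[PROXIMAL], state, 1.0)


class TestEstimatedMovementTime:
    def test_substitution_and_proportionality(self, geometry):
        t = ha.TargetSpec(position=np.array([0.0, 0.0, 0.1]), alpha=0.0, beta=0.0)
        hand = np.zeros(3)
        assert ha.estimate_movement_time(t, hand, 0.5) == pytest.approx(0.2)
        assert ha.estimate_movement_time(t, hand, 1.0) == pytest.approx(0.1)
        assert ha.estimate_movement_time(t, t.position, 0.5) == 0.0
        with pytest.raises(ValueError):
            ha.estimate_movement_time(t, hand, 0.0)


class TestUpdateLaws:
    def test_displacement_and_frequency_forms_agree(self):
        """The two formulations coincide whenever the tick interval equals
        the reciprocal of the loop frequency."""
        rng = np.random.default_rng(0)
        freq = 90.0
        for _ in range(1000):
            prev = rng.uniform(-90, 90, 5)
            gap = rng.uniform(-60, 60, 5)
            remaining = rng.uniform(0.05, 0.8)
            displacement = rng.uniform(0.0, 1.0) * remaining  # pre-overshoot regime
            speed = displacement * freq
            mt_hat = remaining / speed if speed > 0 else np.inf
            a = angular_update(prev, gap, displacement, remaining, clip_fraction=False)
            if speed > 0:
                b = angular_update_by_frequency(prev, gap, mt_hat, freq)
                np.testing.assert_allclose(a, b, atol=1e-9)
            else:
                np.testing.assert_array_equal(a, prev)

    def test_substitution_example(self):
        # gap 10 deg, 1 cm locked displacement, 10 cm remaining -> +1 deg
        out = angular_update(np.array([90.0]), np.array([10.0]), 0.01, 0.10)
        assert out[0] == pytest.approx(91.0)

    def test_zero_displacement_holds_joints(self):
        out = angular_update(np.array([50.0, -20.0]), np.array([30.0, 10.0]), 0.0, 0.2)
        np.testing.assert_array_equal(out, [50.0, -20.0])

    def test_fraction_clipped_so_goal_never_overshot(self):
        # hand displacement larger than remaining distance: land on the goal
        out = angular_update(np.array([0.0]), np.array([10.0]), 0.5, 0.1)
        assert out[0] == pytest.approx(10.0)
        out = angular_update(np.array([0.0]), np.array([10.0]), 0.5, 0.0)
        assert out[0] == pytest.approx(10.0)

    def test_linear_gap_decay_matches_telescoped_closed_form(self):
        """Constant goal, straight-line constant-speed approach: the gap
        shrinks in proportion to the remaining distance."""
        gap0, r0, s = 40.0, 0.5, 0.004
        gap, r = gap0, r0
        while r - s > 0.05 and abs(gap) >= 1.0:
            step = angular_update(np.array([0.0]), np.array([gap]), s, r)[0]
            gap -= step  # remaining angular displacement after the tick
            r -= s  # hand advanced straight toward the target
            assert gap / gap0 == pytest.approx(r / r0, rel=1e-6)


class TestInterpolationStep:
    def test_latch_within_one_degree_tracks_prediction(self, geometry, rom, scenario):
        target, posture, oracle, start, state = scenario
        goal = ha.saturate(oracle.predict_goal(target), rom)
        # place the arm 0.5 deg from the goal on every distal joint
        near = start.copy()
        near[DISTAL] = goal - 0.5
        state = ha.initial_state(geometry, near, time=0.0, target=target)
        out, state = ha.interpolation_step(
            geometry, oracle, rom, target, near[PROXIMAL], state, 1 / 90
        )
        np.testing.assert_allclose(out, goal)
        assert state.latched.all()
        # latched joints keep tracking the prediction even with zero motion
        out2, state = ha.interpolation_step(
            geometry, oracle, rom, target, near[PROXIMAL], state, 2 / 90
        )
        np.testing.assert_allclose(out2, goal)

    def test_zero_motion_holds_distal_indefinitely(self, geometry, rom, scenario):
        target, posture, oracle, start, state = scenario
        for k in range(1, 20):
            out, state = ha.interpolation_step(
                geometry, oracle, rom, target, start[PROXIMAL], state, k / 90
            )
            unlatched = ~state.latched
            np.testing.assert_array_equal(out[unlatched], start[DISTAL][unlatched])

    def test_target_change_without_reset_is_an_error(self, geometry, rom, oracle_setup):
        targets, postures, oracle = oracle_setup
        start = ha.joint_angles(sfe=20, efe=90)
        state = ha.initial_state(geometry, start, time=0.0, target=targets[0])
        with pytest.raises(ValueError):
            ha.interpolation_step(
                geometry, oracle, rom, targets[1], start[PROXIMAL], state, 1 / 90
            )

    def test_reset_clears_latches_but_preserves_continuity(self, geometry, rom, oracle_setup):
        targets, postures, oracle = oracle_setup
        start = ha.joint_angles(sfe=20, efe=90)
        state = ha.initial_state(geometry, start, time=0.0, target=targets[0])
        out, state = ha.interpolation_step(
            geometry, oracle, rom, targets[0], start[PROXIMAL] + 0.5, state, 1 / 90
        )
        reset = ha.reset_on_target_change(state, targets[1])
        assert not reset.latched.any()
        np.testing.assert_array_equal(reset.distal_prev, state.distal_prev)
        np.testing.assert_array_equal(reset.hand_prev, state.hand_prev)
        assert reset.time_prev == state.time_prev
        assert target_key(targets[1]) == reset.target_id
        # same target: latches untouched
        again = ha.reset_on_target_change(reset, targets[1])
        assert again is reset

    def test_outputs_always_within_rom(self, geometry, rom, oracle_setup):
        targets, postures, oracle = oracle_setup
        lo, hi = rom.distal()
        rng = np.random.default_rng(4)
        start = 0.5 * (rom.min_deg + rom.max_deg)
        state = ha.initial_state(geometry, start, time=0.0, target=targets[2])
        prox = start[PROXIMAL].copy()
        for k in range(1, 60):
            prox = prox + rng.uniform(-0.5, 0.5, 2)
            out, state = ha.interpolation_step(
                geometry, oracle, rom, targets[2], prox, state, k / 90
            )
            assert np.all(out >= lo - 1e-9) and np.all(out <= hi + 1e-9)


class TestDirectControl:
    def test_constant_for_fixed_inputs(self, rom, oracle_setup):
        targets, postures, oracle = oracle_setup
        a = ha.direct_step(oracle, rom, targets[0], np.array([10.0, 10.0]))
        b = ha.direct_step(oracle, rom, targets[0], np.array([10.0, 10.0]))
        np.testing.assert_array_equal(a, b)

    def test_equals_interpolation_goal_once_fully_latched(self, geometry, rom, oracle_setup):
        targets, postures, oracle = oracle_setup
        target, posture = targets[3], postures[3]
        state = ha.initial_state(geometry, posture, time=0.0, target=target)
        out, state = ha.interpolation_step(
            geometry, oracle, rom, target, posture[PROXIMAL], state, 1 / 90
        )
        assert state.latched.all()
        np.testing.assert_allclose(
            out, ha.direct_step(oracle, rom, target, posture[PROXIMAL])
        )

    def test_target_switch_jumps_by_full_prediction_gap(self, rom, oracle_setup):
        targets, postures, oracle = oracle_setup
        prox = np.array([10.0, 10.0])
        before = ha.direct_step(oracle, rom, targets[0], prox)
        after = ha.direct_step(oracle, rom, targets[1], prox)
        gap = ha.saturate(oracle.predict_goal(targets[1]), rom) - before
        np.testing.assert_allclose(after - before, gap)
        assert np.max(np.abs(gap)) > 1.0  # a genuine jump for distinct targets
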
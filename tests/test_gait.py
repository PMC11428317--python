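import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sprawlgait.body import GirdleFrame, default_andrias_plan, limb_forward_kinematics, limb_root
from sprawlgait.gait import (
    GaitParams,
    ReachViolation,
    limb_phase,
    max_flag_free_speed,
    plan_footfall,
    simulate,
    solve_limb_ik,
    stance_frame_count,
    stance_height,
    trunk_bend_angles,
)

GIRDLE = GirdleFrame(origin=(0.0, 0.0, 0.1), yaw=0.0)


class TestBendingWave:
    def test_zero_amplitude_gives_zero_angles(self, plan):
        gait = GaitParams(bending_amplitude=0.0)
        for frame in (0, 13, 42, 85):
            assert np.all(trunk_bend_angles(gait, plan, frame) == 0.0)

    def test_total_bend_peaks_at_amplitude(self, plan):
        # with bending_phase 0.25 the sine peaks at frame 0 (couplet touchdown)
        gait = GaitParams(bending_amplitude=22.03, frames_per_stride=85)
        assert trunk_bend_angles(gait, plan, 0).sum() == pytest.approx(22.03)

    def test_zero_crossing_at_quarter_stride_shift(self, plan):
        # half a period after the peak the bend crosses back through the peak's
        # negative; a quarter period after the peak it is zero
        gait = GaitParams(bending_amplitude=59.97, frames_per_stride=80)
        quarter = 20  # frames: sin argument advances by pi/2 from the peak
        assert trunk_bend_angles(gait, plan, quarter).sum() == pytest.approx(
            0.0, abs=1e-9
        )
        half = 40
        assert trunk_bend_angles(gait, plan, half).sum() == pytest.approx(-59.97)

    def test_formula_matches_sine(self, plan):
        gait = GaitParams(bending_amplitude=30.0, frames_per_stride=60, bending_phase=0.1)
        for frame in range(0, 60, 7):
            expected = 30.0 * math.sin(2 * math.pi * (frame / 60 + 0.1))
            assert trunk_bend_angles(gait, plan, frame).sum() == pytest.approx(expected)


class TestLimbPhase:
    def test_stride_start_is_stance(self, default_gait):
        phase, state = limb_phase(default_gait, "LF", 0)
        assert phase == 0.0 and state == "stance"

    def test_duty_factor_threshold(self):
        gait = GaitParams(frames_per_stride=1000, duty_factor=0.52)
        assert limb_phase(gait, "LF", 519)[1] == "stance"
        assert limb_phase(gait, "LF", 521)[1] == "swing"

    def test_couplet_half_stride_shift(self):
        gait = GaitParams(frames_per_stride=80)
        phase, state = limb_phase(gait, "RF", 40)
        assert phase == 0.0 and state == "stance"


class TestInverseKinematics:
    def test_full_reach_is_straight(self, plan):
        root = limb_root(plan, "LF", GIRDLE)
        reach = plan.forelimb_reach
        target = root + np.array([0.0, reach, 0.0])  # straight out to the left
        az, el, flex = solve_limb_ik(plan, "LF", GIRDLE, target)
        assert flex == pytest.approx(0.0, abs=1e-5)

    def test_flexion_matches_law_of_cosines(self, plan):
        """Independent oracle: interior angle from the law of cosines."""
        l1, l2 = plan.femur_length, plan.tibia_length
        root = limb_root(plan, "RH", GIRDLE)
        rng = np.random.default_rng(42)
        for _ in range(1000):
            d = rng.uniform(abs(l1 - l2) + 1e-4, l1 + l2 - 1e-6)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            target = root + d * direction
            _, _, flex = solve_limb_ik(plan, "RH", GIRDLE, target)
            expected = 180.0 - math.degrees(
                math.acos(
                    np.clip((l1**2 + l2**2 - d**2) / (2 * l1 * l2), -1.0, 1.0)
                )
            )
            assert flex == pytest.approx(expected, abs=1e-9)

    def test_fk_ik_round_trip_random_targets(self, plan):
        rng = np.random.default_rng(7)
        for limb in ("LF", "RF", "LH", "RH"):
            l1, l2 = (
                (plan.humerus_length, plan.radius_length)
                if limb[1] == "F"
                else (plan.femur_length, plan.tibia_length)
            )
            girdle = GirdleFrame(origin=(0.3, -0.1, 0.12), yaw=25.0)
            root = limb_root(plan, limb, girdle)
            for _ in range(250):
                d = rng.uniform(abs(l1 - l2) + 1e-4, l1 + l2 - 1e-6)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                target = root + d * direction
                sol = solve_limb_ik(plan, limb, girdle, target)
                _, foot = limb_forward_kinematics(plan, limb, girdle, sol)
                assert np.linalg.norm(foot - target) < 1e-9

    def test_target_beyond_reach_raises_with_shortfall(self, plan):
        root = limb_root(plan, "LH", GIRDLE)
        target = root + np.array([0.0, plan.hindlimb_reach + 0.05, 0.0])
        with pytest.raises(ReachViolation) as err:
            solve_limb_ik(plan, "LH", GIRDLE, target)
        assert err.value.shortfall == pytest.approx(0.05, abs=1e-9)

    @given(
        d_frac=st.floats(0.05, 0.999),
        theta=st.floats(0.0, 2 * math.pi),
        phi=st.floats(-1.2, 0.5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_property(self, d_frac, theta, phi):
        plan = default_andrias_plan()
        root = limb_root(plan, "LH", GIRDLE)
        d = d_frac * plan.hindlimb_reach
        if d < 1e-3:
            return
        direction = np.array(
            [math.cos(phi) * math.cos(theta), math.cos(phi) * math.sin(theta), math.sin(phi)]
        )
        target = root + d * direction
        sol = solve_limb_ik(plan, "LH", GIRDLE, target)
        _, foot = limb_forward_kinematics(plan, "LH", GIRDLE, sol)
        assert np.linalg.norm(foot - target) < 1e-9


class TestFootfallPlanning:
    def test_zero_protraction_anchor_is_lateral(self, plan):
        gait = GaitParams(max_protraction=1e-9)
        anchor = plan_footfall(plan, gait, GIRDLE, "LF")
        root = limb_root(plan, "LF", GIRDLE)
        assert anchor[0] == pytest.approx(root[0], abs=1e-9)
        assert anchor[2] == 0.0

    def test_anchor_reachable_at_touchdown(self, plan, default_gait):
        for limb in ("LF", "RF", "LH", "RH"):
            anchor = plan_footfall(plan, default_gait, GIRDLE, limb)
            # solving IK for the anchor must succeed
            solve_limb_ik(
                plan,
                limb,
                GirdleFrame(
                    origin=(0.0, 0.0, stance_height(plan, default_gait)), yaw=0.0
                ),
                anchor,
            )

    def test_left_right_anchors_mirror(self, plan, default_gait):
        g = GirdleFrame(origin=(0.0, 0.0, stance_height(plan, default_gait)), yaw=0.0)
        a_l = plan_footfall(plan, default_gait, g, "LH")
        a_r = plan_footfall(plan, default_gait, g, "RH")
        np.testing.assert_allclose(a_l * np.array([1, -1, 1]), a_r, atol=1e-12)

    def test_successive_anchors_spaced_by_stride(self, plan, moderate_traj):
        from sprawlgait.metrics import detect_footfalls, stride_lengths

        events = detect_footfalls(moderate_traj, "LF")
        gaps = stride_lengths(events)
        expected = moderate_traj.forward_speed * 85 / 30.0
        np.testing.assert_allclose(gaps, expected, atol=1e-9)


class TestSimulation:
    def test_no_slip_within_stance(self, moderate_traj):
        """Planted feet do not move between consecutive stance frames."""
        from sprawlgait.metrics import contact_mask

        assert moderate_traj.flags == []
        for limb in ("LF", "RF", "LH", "RH"):
            mask = contact_mask(moderate_traj, limb)
            pos = moderate_traj.tracker(f"foot_{limb.lower()}")
            both = mask[:-1] & mask[1:]
            steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)[both]
            assert steps.max() < 1e-6

    def test_speed_consistency(self, moderate_traj):
        """Mean speed equals stride length x stride frequency on unflagged runs."""
        from sprawlgait.metrics import measure_stride_metrics, mean_speed

        m = measure_stride_metrics(moderate_traj)
        v = mean_speed(moderate_traj, "body")
        assert v == pytest.approx(m.stride_length * (30.0 / 85.0), abs=1e-6)
        assert v == pytest.approx(moderate_traj.forward_speed, abs=1e-9)

    def test_duty_factor_recovered(self, moderate_traj):
        from sprawlgait.metrics import duty_factor_measured

        measured = duty_factor_measured(moderate_traj, "LH")
        assert measured == pytest.approx(0.52, abs=1.0 / 85.0)

    def test_couplet_phasing(self, moderate_traj):
        from sprawlgait.metrics import detect_footfalls

        td = {
            limb: [e.frame for e in detect_footfalls(moderate_traj, limb)]
            for limb in ("LF", "RH", "RF", "LH")
        }
        # LF and RH touch down together
        for a, b in zip(td["LF"], td["RH"]):
            assert abs(a - b) <= 1
        # the opposite couplet is shifted by half a stride
        lf = [f for f in td["LF"] if f > 0]
        rf = [f for f in td["RF"] if f > 0]
        for a, b in zip(lf, rf):
            assert abs(abs(a - b) - 85 / 2) <= 1

    def test_periodicity_in_body_frame(self, moderate_traj):
        """After a one-stride warm-up, body-frame tracker paths repeat with the
        stride period."""
        F = 85
        body = moderate_traj.tracker("body")
        for name in ("foot_lh", "foot_rf", "snout", "hip_l"):
            rel = moderate_traj.tracker(name) - body
            np.testing.assert_allclose(rel[F : 2 * F], rel[2 * F : 3 * F], atol=1e-9)

    def test_determinism(self, plan, default_gait):
        a = simulate(plan, default_gait, n_strides=2)
        b = simulate(plan, default_gait, n_strides=2)
        for name in a.tracker_names:
            assert np.array_equal(a.tracker(name), b.tracker(name))

    def test_overspeed_raises_flags_not_errors(self, plan):
        v = max_flag_free_speed(plan, GaitParams())
        gait = replace(GaitParams(), forward_speed=v * 1.3)
        traj = simulate(plan, gait, n_strides=2)
        assert len(traj.flags) > 0
        stance_flags = {limb for _, limb in traj.flags}
        assert stance_flags  # violations surface per limb, run completes

    def test_zero_amplitude_run_is_flag_free(self, straight_traj):
        assert straight_traj.flags == []

    def test_stance_quantization(self, default_gait):
        assert stance_frame_count(default_gait) == 44  # round(0.52 * 85)


class TestFeasibleSpeedSearch:
    def test_straight_gait_has_positive_speed(self, plan):
        gait = GaitParams(bending_amplitude=0.0, frames_per_stride=80)
        assert max_flag_free_speed(plan, gait) > 0

    def test_found_speed_is_maximal(self, plan, default_gait):
        v = max_flag_free_speed(plan, default_gait)
        ok = simulate(plan, replace(default_gait, forward_speed=v), n_strides=3)
        assert ok.flags == []
        bad = simulate(plan, replace(default_gait, forward_speed=v + 0.01), n_strides=3)
        assert bad.flags != []

    def test_longer_limbs_do_not_slow_down(self, plan):
        from dataclasses import replace as dc_replace

        long_limbs = dc_replace(
            plan,
            humerus_length=2 * plan.humerus_length,
            radius_length=2 * plan.radius_length,
            femur_length=2 * plan.femur_length,
            tibia_length=2 * plan.tibia_length,
        )
        gait = GaitParams()
        assert max_flag_free_speed(long_limbs, gait) >= max_flag_free_speed(plan, gait)
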
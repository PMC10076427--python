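"""Clamp controller: target trajectories, model inversion, recalibration, gate."""

from dataclasses import replace

import numpy as np
import pytest

import asalab as al
from asalab.clamp import ClampSession, DECLINE_MG_DL_MIN, SALINE_RATE_ML_H
from asalab.pharmacokinetics import PKState


class TestTargetTrajectory:
    def test_alcohol_reward_ramps_13_in_3_minutes(self):
        traj = al.TargetTrajectory(t0=0.0, v0=58.0)
        traj = al.extend_target_for_reward(traj, 10.0, "alcohol")
        assert traj.value(10.0) == pytest.approx(50.0)  # 58 - 0.8*10
        assert traj.value(13.0) == pytest.approx(63.0)
        assert traj.value(13.0 + 5.0) == pytest.approx(63.0 - 4.0)

    def test_decline_without_reward(self):
        traj = al.TargetTrajectory(t0=10.0, v0=50.0)
        assert traj.value(20.0) == pytest.approx(42.0)

    def test_decline_floors_at_zero(self):
        traj = al.TargetTrajectory(t0=0.0, v0=4.0)
        assert traj.value(10.0) == 0.0

    def test_saline_reward_leaves_target_unchanged(self):
        traj = al.TargetTrajectory(t0=0.0, v0=40.0)
        before = [traj.value(t) for t in (0, 5, 10)]
        traj = al.extend_target_for_reward(traj, 2.0, "saline")
        assert [traj.value(t) for t in (0, 5, 10)] == before
        assert traj.reward_events == ((2.0, "saline"),)

    def test_reward_before_last_ramp_end_rejected(self):
        traj = al.extend_target_for_reward(al.TargetTrajectory(), 5.0, "alcohol")
        with pytest.raises(ValueError):
            al.extend_target_for_reward(traj, 6.0, "alcohol")


class TestFeedforwardRate:
    def _controller(self, params, brac=50.0):
        state = PKState(t=0.0, c_central=brac / 100.0, c_peripheral=brac / 100.0)
        return al.ControllerState(params_est=params, model=state)

    def test_infuses_to_slow_a_too_fast_fall(self, default_pk):
        # equilibrated at 50 mg/dL with a huge vmax: natural fall outpaces -0.8
        fast = replace(default_pk, vmax_g_min=default_pk.vmax_g_min * 20)
        ctrl = self._controller(fast)
        traj = al.TargetTrajectory(t0=0.0, v0=50.0)
        cmd = al.feedforward_rate(ctrl, traj, 0.0, 0.05)
        assert cmd.rate_ml_h > 0.0

    def test_saturates_at_zero_when_target_falls_faster_than_model(self, default_pk):
        # tiny vmax: equilibrated elimination declines far slower than 0.8
        # mg/dL/min, and ethanol cannot be extracted through the pump
        slow = replace(default_pk, vmax_g_min=default_pk.vmax_g_min / 20)
        ctrl = self._controller(slow)
        traj = al.TargetTrajectory(t0=0.0, v0=50.0)
        cmd = al.feedforward_rate(ctrl, traj, 0.0, 0.05)
        assert cmd.rate_ml_h == 0.0

    def test_tracking_error_under_true_parameters(self, default_pk):
        """Noiseless controller with the true model tracks the prescribed
        path to well under 2 mg/dL over a 150-min session."""
        sim = ClampSession(default_pk, t0=0.0, dt_min=0.05)
        sim.advance(5.0)
        for _ in range(14):
            sim.start_reward("alcohol")
            sim.advance(3.0)
            sim.advance(7.0)
        errors = [abs(sim.traj.value(t) - b) for t, b in sim.brac_series if t > 0]
        assert max(errors) <= 2.0


class TestRecalibrate:
    def _controller(self, params, brac=60.0):
        state = PKState(t=0.0, c_central=brac / 100.0, c_peripheral=brac / 100.0)
        return al.ControllerState(params_est=params, model=state)

    def test_reading_equal_to_prediction_leaves_estimate_unchanged(self, default_pk):
        ctrl = self._controller(default_pk)
        out = al.recalibrate(ctrl, al.BrACReading(t=1.0, brac=60.0))
        assert out.params_est.vmax_g_min == pytest.approx(default_pk.vmax_g_min)

    def test_reading_above_prediction_lowers_elimination_estimate(self, default_pk):
        ctrl = self._controller(default_pk)
        out = al.recalibrate(ctrl, al.BrACReading(t=1.0, brac=66.0))
        assert out.params_est.vmax_g_min < default_pk.vmax_g_min

    def test_update_bounded_to_thirty_percent(self, default_pk):
        ctrl = self._controller(default_pk)
        out = al.recalibrate(ctrl, al.BrACReading(t=1.0, brac=600.0))
        assert out.params_est.vmax_g_min == pytest.approx(0.7 * default_pk.vmax_g_min)

    def test_out_of_order_readings_rejected(self, default_pk):
        ctrl = self._controller(default_pk)
        ctrl = al.recalibrate(ctrl, al.BrACReading(t=10.0, brac=60.0))
        with pytest.raises(ValueError):
            al.recalibrate(ctrl, al.BrACReading(t=5.0, brac=60.0))

    def test_recalibration_shrinks_tracking_error_of_mismatched_model(self, default_pk):
        """Against a subject with perturbed vmax, periodic recalibration beats
        running open-loop on the wrong estimate."""
        true = replace(default_pk, vmax_g_min=default_pk.vmax_g_min * 1.5)

        def run(interval):
            sim = ClampSession(
                true,
                est_params=default_pk,
                t0=0.0,
                dt_min=0.05,
                reading_interval_min=interval,
                reading_noise_sd=0.0,
            )
            sim.advance(2.0)
            for _ in range(10):
                sim.start_reward("alcohol")
                sim.advance(10.0)
            errors = [abs(sim.traj.value(t) - b) for t, b in sim.brac_series]
            return float(np.mean(errors))

        assert run(20.0) < run(1e9)


class TestRewardEligibility:
    @pytest.mark.parametrize(
        "brac,expected", [(160.0, True), (170.0, False), (167.0, True)]
    )
    def test_gate_is_inclusive_at_the_limit(self, brac, expected):
        assert al.reward_eligible(brac, 180.0) is expected

    def test_accepts_pk_state(self):
        assert al.reward_eligible(PKState(c_central=1.0)) is True

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError):
            al.reward_eligible(100.0, 0.0)


class TestClampFidelity:
    def test_single_reward_increment(self, default_pk):
        """One alcohol reward raises simulated BrAC by 13 +- 0.5 mg/dL in 3 min."""
        start = PKState(t=0.0, c_central=0.40, c_peripheral=0.40)
        sim = ClampSession(default_pk, t0=0.0, initial_state=start, dt_min=0.05)
        sim.advance(2.0)
        b0 = sim.brac
        sim.start_reward("alcohol")
        sim.advance(3.0)
        assert sim.brac - b0 == pytest.approx(13.0, abs=0.5)

    def test_inter_reward_decline_slope(self, default_pk):
        sim = ClampSession(default_pk, t0=0.0, dt_min=0.05)
        sim.start_reward("alcohol")
        sim.advance(3.0)
        sim.start_reward("alcohol")
        sim.advance(3.0)
        sim.advance(12.0)
        pts = np.array([(t, b) for t, b in sim.brac_series if 6.5 <= t <= 18.0])
        slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
        assert slope == pytest.approx(-DECLINE_MG_DL_MIN, abs=0.05)

    def test_saline_reward_delivers_15_ml_over_3_min(self, default_pk):
        sim = ClampSession(default_pk, t0=0.0, dt_min=0.05)
        sim.start_reward("saline")
        sim.advance(5.0)
        frame = sim.infusion_frame()
        saline = frame[frame.kind == "saline"]
        assert saline.rate_ml_h.max() <= SALINE_RATE_ML_H
        volume_ml = (saline.rate_ml_h / 60.0 * 0.05).sum()
        assert volume_ml == pytest.approx(15.0, rel=0.02)
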
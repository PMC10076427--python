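"""Session engine: schedule calibration, the adaptive attention task, and
full-session execution."""

import math
from collections import defaultdict
from dataclasses import replace

import numpy as np
import pytest

import asalab as al
from asalab.session import (
    CATConfig,
    LatencyModel,
    WorkSchedule,
    adapt_window,
    calibrate_schedule,
    futility_index,
    required_trials,
    run_cat_trial,
)


class TestSchedule:
    def test_calibrated_defaults(self):
        ws = calibrate_schedule()
        assert ws.n1 == 4
        assert ws.ratio == pytest.approx(1.3174, abs=0.001)
        assert required_trials(ws, 1) == 4
        assert required_trials(ws, 2) == 5
        assert required_trials(ws, 15) == 189

    def test_requirements_strictly_increasing(self):
        ws = calibrate_schedule()
        reqs = [required_trials(ws, k) for k in range(1, 30)]
        assert all(b > a for a, b in zip(reqs, reqs[1:]))

    def test_index_below_one_rejected(self):
        with pytest.raises(IndexError):
            required_trials(WorkSchedule(), 0)

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(al.CalibrationError):
            calibrate_schedule(first_duration_s=7.3, last_duration_min=7.3 / 60.0)

    def test_scale_invariance_under_trial_duration(self):
        slow = calibrate_schedule(mean_trial_s=14.6)
        fast = calibrate_schedule(mean_trial_s=7.3)
        assert slow.n1 == fast.n1 // 2
        assert slow.ratio == pytest.approx(fast.ratio, abs=0.01)

    def test_futility_index_at_defaults(self):
        ws = calibrate_schedule()
        assert futility_index(ws) == 14
        # one set earlier, working still pays: 109 trials * 7.3 s * 0.8/min < 13
        cost_13 = required_trials(ws, 13) * 7.3 / 60.0 * 0.8
        assert cost_13 < 13.0

    def test_futility_never_without_decline(self):
        assert futility_index(WorkSchedule(), decline=0.0) == math.inf

    def test_futility_monotone_in_reward_increment(self):
        ws = WorkSchedule()
        assert futility_index(ws, reward_increment=26.0) > futility_index(ws)


class TestAttentionTask:
    def test_infinite_window_always_succeeds(self):
        rng = np.random.default_rng(0)
        cat, lat = CATConfig(), LatencyModel()
        assert all(run_cat_trial(cat, lat, math.inf, rng)[2] for _ in range(100))

    def test_zero_window_always_fails(self):
        rng = np.random.default_rng(0)
        cat, lat = CATConfig(), LatencyModel()
        assert not any(run_cat_trial(cat, lat, 0.0, rng)[2] for _ in range(100))

    def test_symmetric_staircase_returns_after_one_up_one_down(self):
        cat = CATConfig(window_up=1.25, window_down=0.8)  # up = 1/down
        w = adapt_window(cat, adapt_window(cat, 0.5, True), False)
        assert w == pytest.approx(0.5)

    def test_equilibrium_success_probability_matches_detailed_balance(self):
        cat = CATConfig()
        p = cat.equilibrium_success
        assert p * math.log(cat.window_down) + (1 - p) * math.log(cat.window_up) == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(cat.success_target, abs=0.05)

    def test_staircase_holds_success_rate_near_target(self):
        rng = np.random.default_rng(7)
        cat, lat = CATConfig(), LatencyModel()
        window = cat.initial_window_s
        hits = 0
        n = 10_000
        for _ in range(n):
            _, _, success = run_cat_trial(cat, lat, window, rng)
            window = adapt_window(cat, window, success)
            hits += success
        assert hits / n == pytest.approx(cat.success_target, abs=0.05)

    def test_staircase_compensates_an_impaired_agent(self):
        """With slowed latencies, the window grows until the success rate recovers."""
        rng = np.random.default_rng(11)
        cat = CATConfig()
        sober, drunk = LatencyModel(), LatencyModel(base_s=0.28 * 1.8)
        window = cat.initial_window_s
        for _ in range(2000):  # converge under impairment
            _, _, success = run_cat_trial(cat, drunk, window, rng)
            window = adapt_window(cat, window, success)
        hits = 0
        for _ in range(4000):
            _, _, success = run_cat_trial(cat, drunk, window, rng)
            window = adapt_window(cat, window, success)
            hits += success
        assert hits / 4000 == pytest.approx(cat.success_target, abs=0.07)
        assert window > cat.initial_window_s


class TestRunSession:
    def test_never_working_agent_earns_nothing(self, default_male, default_pk, noiseless_session_config):
        log = al.run_session(
            default_male, default_pk, al.scripted_agent("never_work"),
            noiseless_session_config, seed=1,
        )
        assert al.cumulative_work(log, "alcohol") == 0
        assert al.cumulative_work(log, "saline") == 0
        frame = log.brac_frame()
        # priming alcohol decays toward zero with nothing earned
        assert frame.brac_mg_dl.iloc[-1] < frame[frame.t_min <= 0].brac_mg_dl.max()

    def test_replay_is_bit_identical(self, default_male, default_pk, noiseless_session_config):
        a = al.run_session(default_male, default_pk, al.BehavioralAgent(),
                           noiseless_session_config, seed=9)
        b = al.run_session(default_male, default_pk, al.BehavioralAgent(),
                           noiseless_session_config, seed=9)
        assert a.events == b.events
        assert a.brac_series == b.brac_series
        assert a.assessments == b.assessments

    def test_events_are_time_ordered(self, always_work_log):
        times = [e.t for e in always_work_log.events]
        assert all(b >= a - 1e-9 for a, b in zip(times, times[1:]))

    def test_completed_worksets_contain_exactly_the_required_successes(self, always_work_log):
        ws = al.WorkSchedule()
        successes = defaultdict(int)
        for e in always_work_log.events:
            if e.t < 0 or e.workset_index is None:
                continue
            if e.kind == "trial_success":
                successes[(e.reward_kind, e.workset_index)] += 1
            elif e.kind == "workset_complete":
                assert successes[(e.reward_kind, e.workset_index)] == required_trials(
                    ws, e.workset_index
                )

    def test_brac_at_t0_reflects_decline_through_the_wait(self, default_male, default_pk,
                                                          noiseless_session_config):
        log = al.run_session(default_male, default_pk, al.scripted_agent("never_work"),
                             noiseless_session_config, seed=1)
        frame = log.brac_frame()
        priming_end = max(e.t for e in log.events if e.kind == "reward_end")
        b_end = float(np.interp(priming_end, frame.t_min, frame.brac_mg_dl))
        b_zero = float(np.interp(0.0, frame.t_min, frame.brac_mg_dl))
        assert b_end - b_zero == pytest.approx(0.8 * (0.0 - priming_end), abs=0.5)

    def test_ascending_then_plateau_shape(self, always_work_log):
        """Relentless work gives a BrAC path that rises over the first hour
        and flattens or declines over the last 50 minutes."""
        frame = always_work_log.brac_frame()
        vwr = frame[frame.t_min >= 0]
        first = vwr[vwr.t_min <= 60.0]
        last = vwr[vwr.t_min >= 100.0]
        assert np.polyfit(first.t_min, first.brac_mg_dl, 1)[0] > 0
        assert np.polyfit(last.t_min, last.brac_mg_dl, 1)[0] <= 0

    def test_alternating_agent_advances_both_progressions_in_lockstep(
        self, default_male, default_pk, noiseless_session_config
    ):
        log = al.run_session(default_male, default_pk, al.scripted_agent("alternating"),
                             noiseless_session_config, seed=4)
        completed = defaultdict(list)
        for e in log.events:
            if e.kind == "workset_complete" and e.t >= 0:
                completed[e.reward_kind].append(e.workset_index)
        assert completed["alcohol"] == sorted(completed["alcohol"])
        assert completed["saline"] == sorted(completed["saline"])
        assert abs(len(completed["alcohol"]) - len(completed["saline"])) <= 1
        # requirement sequence per kind is untouched by interleaving
        for kind in ("alcohol", "saline"):
            assert completed[kind] == list(range(1, len(completed[kind]) + 1))

    def test_always_work_session_matches_hand_simulation(self, default_male, default_pk):
        """Event accounting cross-check: an independent event-by-event
        bookkeeping loop over the same random stream yields the same number
        of completed work-sets."""
        cfg = al.SessionConfig(
            reading_noise_sd=0.0,
            priming_saline=0,
            priming_alcohol=0,
            safety_limit=1000.0,
            latency=LatencyModel(impair_per_mg_dl=0.0),
        )
        seed = 5
        log = al.run_session(default_male, default_pk, al.scripted_agent("always_alcohol"),
                             cfg, seed=seed)
        engine_sets = sum(
            1 for e in log.events
            if e.kind == "workset_complete" and e.reward_kind == "alcohol" and e.t < 150.0
        )
        engine_trials = al.cumulative_work(log, "alcohol")

        rng = np.random.default_rng(seed)
        t, window = 0.0, cfg.cat.initial_window_s
        completed = trials = successes = 0
        k = 1
        while t < 150.0 - 1e-9:
            duration, _, success = run_cat_trial(cfg.cat, cfg.latency, window, rng)
            t += duration / 60.0
            window = adapt_window(cfg.cat, window, success)
            if t < 150.0:
                trials += success
            successes += success
            if successes >= required_trials(cfg.schedule, k):
                if t < 150.0:
                    completed += 1
                t += 3.0
                k += 1
                successes = 0
        assert engine_sets == completed
        assert engine_trials == trials

    def test_log_round_trips_through_json(self, always_work_log, tmp_path):
        path = tmp_path / "log.json"
        always_work_log.to_json(path)
        back = al.SessionLog.from_json(path)
        assert back.events == always_work_log.events
        assert back.assessments == always_work_log.assessments
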
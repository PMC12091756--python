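"""Session/day logic: escalation, termination, advancement, scheduling."""

import numpy as np
import pytest

from headfix.mouse_agent import AgentParams, MouseAgent
from headfix.protocol import (
    AdvancementCriterion,
    EscalationSchedule,
    InvalidParameterError,
    TaskKind,
    default_protocol,
)
from headfix.session_manager import (
    AnimalState,
    CageState,
    SessionRecord,
    duration_bounds,
    evaluate_advancement,
    run_day,
    run_habituation_entry,
    run_session,
    session_should_end,
    simulate_cohort,
)
from headfix.trial_engine import Outcome, write_trial_log


SCHED = EscalationSchedule()


class TestDurationBounds:
    @pytest.mark.parametrize(
        "count,expected",
        [
            (0, (0.5, 0.5)),
            (4, (0.5, 0.5)),
            (5, (0.75, 1.0)),
            (399, (3.0, 30.0)),   # uncapped would be 20.25 and 40.0
        ],
    )
    def test_examples(self, count, expected):
        assert duration_bounds(count, SCHED) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            duration_bounds(-1, SCHED)

    def test_monotone_and_capped(self):
        prev = (0.0, 0.0)
        for count in range(1001):
            lo, hi = duration_bounds(count, SCHED)
            assert lo >= prev[0] and hi >= prev[1]
            assert lo <= SCHED.cap_min_min and hi <= SCHED.cap_max_min
            prev = (lo, hi)

    def test_min_cap_first_reached_at_session_50(self):
        # brute-force scan for the first count where the 3 min cap binds
        first = next(c for c in range(1000)
                     if duration_bounds(c, SCHED)[0] == SCHED.cap_min_min)
        assert first == 50


H, M, I = Outcome.HIT, Outcome.MISS, Outcome.INCORRECT


class TestSessionShouldEnd:
    def test_never_ends_before_minimum(self):
        assert session_should_end(0.3, (0.5, 0.5), [M] * 5) == (False, None)

    def test_five_nonhits_after_minimum(self):
        end, reason = session_should_end(2.0, (1.0, 5.0), [H, M, I, M, M, I])
        assert end and reason == "no_hits_in_5"

    def test_hit_in_last_five_continues(self):
        assert session_should_end(2.0, (1.0, 5.0), [M, M, H, M, M]) == (False, None)

    def test_max_duration_boundary(self):
        assert session_should_end(5.0, (1.0, 5.0), [H]) == (True, "max_duration")


def _fake_session(stage_id="D1", index=0):
    return SessionRecord(
        animal_id="a", stage_id=stage_id, session_index=index, day_index=0,
        min_duration_min=1, max_duration_min=5,
        actual_duration_min=3, trials=[], end_reason="max_duration",
    )


class TestEvaluateAdvancement:
    WINDOW = AdvancementCriterion(kind="window_hitrate", window_size=50, hitrate_min=0.8)
    COUNT = AdvancementCriterion(kind="session_count", trials_min=50,
                                 sessions_required=5, lookback_sessions=10)

    def _animal_with_outcome_sessions(self, outcome_lists, stage_id="D1"):
        from headfix.trial_engine import TrialRecord, ToneStimulus, Direction

        def rec(o):
            return TrialRecord(
                animal_id="a", stage_id=stage_id, task=TaskKind.DISCRIMINATION,
                stimulus=ToneStimulus(10000, 70, 2),
                required_direction=Direction.RIGHT,
                choice=Direction.RIGHT if o is H else Direction.NONE,
                outcome=o, latency_s=None, tone_truncated_at_s=None,
                reward_ul=0, timeout_applied_s=0, tactile_applied_s=0,
                bias_corrected=False)

        a = AnimalState(animal_id="a")
        for i, outcomes in enumerate(outcome_lists):
            s = _fake_session(stage_id, i)
            s.trials = [rec(o) for o in outcomes]
            a.session_history.append(s)
        return a

    def test_fifty_straight_hits_advances(self):
        a = self._animal_with_outcome_sessions([[H] * 50])
        assert evaluate_advancement(a, self.WINDOW)

    def test_best_window_below_threshold_does_not_advance(self, rng):
        # 60 trials whose best 50-window holds 39 hits (0.78 < 0.8)
        outcomes = [H] * 39 + [M] * 21
        rng.shuffle(outcomes)
        a = self._animal_with_outcome_sessions([outcomes])
        assert not evaluate_advancement(a, self.WINDOW)

    def test_session_count_criterion(self):
        counts = [60, 10, 55, 51, 9, 70, 50, 8, 12, 50]
        a = self._animal_with_outcome_sessions([[H] * c for c in counts], stage_id="D3")
        assert evaluate_advancement(a, self.COUNT)
        a2 = self._animal_with_outcome_sessions([[H] * c for c in [10, 10, 55, 51]],
                                                stage_id="D3")
        assert not evaluate_advancement(a2, self.COUNT)

    def test_terminal_stage_never_advances(self):
        a = self._animal_with_outcome_sessions([[H] * 100])
        assert not evaluate_advancement(a, AdvancementCriterion(kind="none"))

    def test_window_kind_matches_brute_force(self, rng):
        crit = AdvancementCriterion(kind="window_hitrate", window_size=10,
                                    hitrate_min=0.8)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            outcomes = [H if rng.random() < 0.7 else M for _ in range(n)]
            a = self._animal_with_outcome_sessions([outcomes])
            brute = any(
                sum(o is H for o in outcomes[i:i + 10]) / 10 >= 0.8
                for i in range(max(0, n - 10 + 1))
            ) if n >= 10 else False
            assert evaluate_advancement(a, crit) == brute


class TestHabituationEntry:
    def _agent(self, **kw):
        return MouseAgent(AgentParams(**kw), animal_id="a")

    def test_ten_second_hold_earns_five_drops(self, proto, rng):
        rec = run_habituation_entry(self._agent(), "HF2", proto, rng, holds_s=[10.0])
        assert rec.drops_per_hold == [5]
        assert 25 <= rec.water_ul <= 35  # 5 drops of 5-7 ul

    def test_three_second_hold_earns_one_drop(self, proto, rng):
        rec = run_habituation_entry(self._agent(), "HF2", proto, rng, holds_s=[3.0])
        assert rec.drops_per_hold == [1]

    def test_withdrawal_resets_counter(self, proto, rng):
        rec = run_habituation_entry(self._agent(), "HF2", proto, rng, holds_s=[1.0, 4.0])
        assert rec.drops_per_hold == [0, 2]

    def test_hf3_completed_fixation_earns_five_drops(self, proto, rng):
        rec = run_habituation_entry(self._agent(abort_prob=0.0), "HF3", proto, rng,
                                    holds_s=[10.0])
        assert rec.drops_per_hold == [5]
        assert rec.duration_s >= 10.0  # ~1.5-2 s extension + 5 drops at 2 s

    def test_hf3_abort_earns_nothing(self, proto, rng):
        rec = run_habituation_entry(self._agent(abort_prob=1.0), "HF3", proto, rng,
                                    holds_s=[10.0])
        assert rec.drops_per_hold == [0]

    def test_rejects_non_habituation_stage(self, proto, rng):
        with pytest.raises(InvalidParameterError):
            run_habituation_entry(self._agent(), "D1", proto, rng)


class TestRunSession:
    def test_min_equals_max_ends_at_max_duration(self, proto, rng):
        animal = AnimalState(animal_id="a")
        agent = MouseAgent(AgentParams(lapse=0, disc_miss_prob=0,
                                       disc_slope_octave=0.02))
        rec = run_session(animal, agent, proto.stage("D1"), proto, rng)
        assert rec.end_reason == "max_duration"
        assert rec.actual_duration_min >= 0.5
        assert animal.lifetime_session_count == 1

    def test_nonresponder_ends_no_hits_shortly_after_minimum(self, rng):
        from dataclasses import replace

        proto = default_protocol()
        proto = replace(proto, escalation=EscalationSchedule(
            start_min_min=1.0, start_max_min=5.0))
        animal = AnimalState(animal_id="a")
        agent = MouseAgent(AgentParams(disc_miss_prob=1.0))
        rec = run_session(animal, agent, proto.stage("D1"), proto, rng)
        assert rec.end_reason == "no_hits_in_5"
        assert 1.0 <= rec.actual_duration_min < 1.6
        assert rec.n_hits == 0

    def test_budget_exhaustion_overrides_minimum(self, proto, rng):
        animal = AnimalState(animal_id="a")
        agent = MouseAgent(AgentParams())
        rec = run_session(animal, agent, proto.stage("D1"), proto, rng,
                          remaining_budget_min=0.2)
        assert rec.end_reason == "budget_exhausted"
        assert rec.actual_duration_min < 0.5

    def test_no_trial_starts_after_max_bound(self, proto, rng):
        animal = AnimalState(animal_id="a", lifetime_session_count=20)
        agent = MouseAgent(AgentParams())
        rec = run_session(animal, agent, proto.stage("D5"), proto, rng)
        start = 0.0
        for t in rec.trials:
            assert start < rec.max_duration_min
            start += t.duration_s / 60.0

    def test_lifetime_counter_and_history_grow_by_one(self, proto, rng):
        animal = AnimalState(animal_id="a")
        agent = MouseAgent(AgentParams())
        for k in range(1, 4):
            run_session(animal, agent, proto.stage("D1"), proto, rng)
            assert animal.lifetime_session_count == k
            assert len(animal.session_history) == k


class TestRunDay:
    def test_budget_is_forty_minutes_per_mouse(self):
        cage = CageState(animals=[AnimalState(animal_id=f"a{i}") for i in range(3)])
        assert cage.daily_budget_min == 120.0

    def test_empty_cage_rejected(self, proto):
        with pytest.raises(InvalidParameterError):
            run_day(CageState(animals=[]), {}, proto, {})

    def test_fixation_time_conserved_within_budget(self, proto):
        result = simulate_cohort(proto, n_animals=3, n_days=1, seed=7)
        day = result.days[0]
        total = sum(s["fixation_min"] for s in day.per_animal.values())
        assert total <= day.budget_min + 0.5  # last session may slightly overrun
        assert day.elapsed_min <= day.budget_min

    def test_habituation_days_progress_stages(self, proto):
        result = simulate_cohort(proto, n_animals=2, n_days=10, seed=3,
                                 start_at="HF1")
        stages = [a.habituation_stage for a in result.cage.animals]
        # 4 days HF1 + 2 days HF2 + 3 days HF3 = HF4 from day 10 on
        assert stages == ["HF4", "HF4"]
        assert any(d.habituation_entries for d in result.days)

    def test_same_seed_reproduces_trial_log(self, proto):
        import io

        logs = []
        for _ in range(2):
            result = simulate_cohort(proto, n_animals=3, n_days=2, seed=11)
            buf = io.StringIO()
            write_trial_log(result.trials, buf)
            logs.append(buf.getvalue())
        assert logs[0] == logs[1]

    def test_satiated_animals_stop_entering(self, proto):
        params = [AgentParams(daily_water_target_ul=100.0) for _ in range(2)]
        result = simulate_cohort(proto, n_animals=2, n_days=1, seed=5,
                                 cohort_params=params)
        day = result.days[0]
        # tiny water target: the day ends long before the budget is used up
        assert day.elapsed_min < day.budget_min / 2
        for aid, summ in day.per_animal.items():
            assert summ["water_ul"] >= 100.0 or summ["n_sessions"] == 0
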
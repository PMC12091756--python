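"""Voluntary head-fixation sessions, days, and stage progression.

A cage of RFID-tagged mice shares one head-fixation tunnel for a fixed
daily access budget (40 min times the number of mice).  Animals enter the
tunnel voluntarily; in HF4 each completed fixation starts a behavioral
session whose minimum/maximum duration escalates with the animal's lifetime
session count.  A session must reach its minimum duration and then ends
when the maximum is reached or when the last five trials contain no hit.
Stage advancement follows each stage's criterion (windowed hit rate or
per-session trial counts over a lookback).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .protocol import (
    AdvancementCriterion,
    EscalationSchedule,
    InvalidParameterError,
    ProtocolConfig,
    StageSpec,
    TaskKind,
)
from .trial_engine import BiasState, Outcome, TrialRecord, run_trial
from .mouse_agent import MouseAgent

#: wall-clock overhead charged per tunnel entry (body transit + RFID read)
ENTRY_TRANSIT_MIN = 0.1
#: anchor-bar fixation attempt duration range (s)
FIXATION_ATTEMPT_S = (1.5, 2.0)
#: habituation mini-fixation: drops dispensed at this interval, up to a cap
HABITUATION_DROP_INTERVAL_S = 2.0
HABITUATION_MAX_DROPS = 5


@dataclass
class SessionRecord:
    """One voluntary head-fixation bout of behavioral trials."""

    animal_id: str
    stage_id: str
    session_index: int          # per animal, lifetime
    day_index: int
    min_duration_min: float
    max_duration_min: float
    actual_duration_min: float
    trials: list[TrialRecord]
    end_reason: str             # max_duration | no_hits_in_5 | budget_exhausted

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_hits(self) -> int:
        return sum(1 for t in self.trials if t.outcome is Outcome.HIT)

    @property
    def outcomes(self) -> list[Outcome]:
        return [t.outcome for t in self.trials]


@dataclass
class HabituationEntryRecord:
    """One HF2/HF3 tunnel visit: head holds and the water drops they earned."""

    animal_id: str
    stage_id: str
    hold_durations_s: list[float]
    drops_per_hold: list[int]
    water_ul: float
    duration_s: float

    @property
    def total_drops(self) -> int:
        return sum(self.drops_per_hold)


@dataclass
class AnimalState:
    """Per-animal (RFID-keyed) progression state."""

    animal_id: str
    task: TaskKind = TaskKind.DISCRIMINATION
    habituation_stage: str = "HF4"
    task_stage_index: int = 0
    lifetime_session_count: int = 0
    session_history: list[SessionRecord] = field(default_factory=list)
    water_consumed_today_ul: float = 0.0
    mapping: str = "default"
    days_in_habituation_stage: int = 0

    def current_stage(self, config: ProtocolConfig) -> StageSpec:
        stages = config.stages_for(self.task)
        return stages[min(self.task_stage_index, len(stages) - 1)]


@dataclass
class CageState:
    """A cage of animals sharing one tunnel under a daily time budget."""

    animals: list[AnimalState]
    budget_min_per_mouse: float = 40.0
    elapsed_min: float = 0.0

    @property
    def daily_budget_min(self) -> float:
        return self.budget_min_per_mouse * len(self.animals)


@dataclass
class DayRecord:
    """One simulated day of cage access."""

    day_index: int
    budget_min: float
    elapsed_min: float
    sessions: list[SessionRecord]
    habituation_entries: list[HabituationEntryRecord]
    per_animal: dict[str, dict]   # n_sessions, fixation_min, n_trials, water_ul


def duration_bounds(
    lifetime_session_count: int, schedule: EscalationSchedule
) -> tuple[float, float]:
    """(min, max) session duration in force after ``count`` completed sessions.

    One increment is applied per ``sessions_per_increment`` completed
    sessions; both bounds are clamped at their caps.
    """
    if lifetime_session_count < 0:
        raise InvalidParameterError("session count cannot be negative")
    k = lifetime_session_count // schedule.sessions_per_increment
    lo = min(schedule.start_min_min + k * schedule.inc_min_min, schedule.cap_min_min)
    hi = min(schedule.start_max_min + k * schedule.inc_max_min, schedule.cap_max_min)
    return lo, hi


def session_should_end(
    elapsed_min: float,
    bounds: tuple[float, float],
    recent_outcomes: Sequence[Outcome],
) -> tuple[bool, str | None]:
    """Session-termination rule, checked after every trial and on clock ticks.

    The minimum duration must be reached first; after that the session ends
    at the maximum duration, or as soon as the last five completed trials
    contain no hit.
    """
    lo, hi = bounds
    if elapsed_min < lo:
        return False, None
    if elapsed_min >= hi:
        return True, "max_duration"
    if len(recent_outcomes) >= 5 and all(
        o is not Outcome.HIT for o in recent_outcomes[-5:]
    ):
        return True, "no_hits_in_5"
    return False, None


def _session_has_qualifying_window(
    outcomes: Sequence[Outcome], window: int, hitrate_min: float
) -> bool:
    n = len(outcomes)
    if n < window:
        return False
    need = hitrate_min * window
    count = sum(1 for o in outcomes[:window] if o is Outcome.HIT)
    if count >= need - 1e-12:
        return True
    for i in range(window, n):
        count += (outcomes[i] is Outcome.HIT) - (outcomes[i - window] is Outcome.HIT)
        if count >= need - 1e-12:
            return True
    return False


def evaluate_advancement(animal: AnimalState, criterion: AdvancementCriterion) -> bool:
    """Whether the animal's history satisfies the stage's advancement rule.

    Only sessions performed in the animal's current stage are considered.
    """
    if criterion.kind == "none":
        return False
    stage_id = None
    if animal.session_history:
        stage_id = animal.session_history[-1].stage_id
    history = [s for s in animal.session_history if s.stage_id == stage_id]
    if criterion.kind == "window_hitrate":
        return any(
            _session_has_qualifying_window(
                s.outcomes, criterion.window_size, criterion.hitrate_min
            )
            for s in history
        )
    recent = history[-criterion.lookback_sessions:]
    qualifying = sum(1 for s in recent if s.n_trials >= criterion.trials_min)
    return qualifying >= criterion.sessions_required


def run_habituation_entry(
    agent: MouseAgent,
    stage_id: str,
    config: ProtocolConfig,
    rng: np.random.Generator,
    holds_s: Sequence[float] | None = None,
) -> HabituationEntryRecord:
    """One HF2/HF3 tunnel visit.

    HF2: while the head-entry beam stays broken, one drop is dispensed
    every 2 s (first drop after 2 s of holding) up to 5 drops; withdrawing
    resets the counter, and the animal may re-hold several times within one
    visit.  HF3: drops require a completed head fixation (the anchor bar
    extends over ~1.5-2 s); a completed fixation delivers 5 drops at 2 s
    intervals, i.e. about a 10 s fixation.
    """
    if stage_id not in ("HF2", "HF3"):
        raise InvalidParameterError(f"habituation entries apply to HF2/HF3, not {stage_id}")
    lo, hi = config.reward_volume_ul_range
    holds: list[float] = []
    drops: list[int] = []
    water = 0.0
    duration = 0.0
    if holds_s is None:
        holds_s = [agent.hold_duration_s(rng)]
        while agent.chains_again(rng) and len(holds_s) < 20:
            holds_s.append(agent.hold_duration_s(rng))
    for hold in holds_s:
        if stage_id == "HF2":
            n = min(HABITUATION_MAX_DROPS, int(hold // HABITUATION_DROP_INTERVAL_S))
            duration += hold + 1.0  # 1 s to re-initiate after withdrawal
        else:  # HF3: anchor extends, then a completed fixation earns 5 drops
            attempt = float(rng.uniform(*FIXATION_ATTEMPT_S))
            if agent.aborts_fixation(rng):
                n = 0
                duration += attempt + 1.0
            else:
                n = HABITUATION_MAX_DROPS
                duration += attempt + n * HABITUATION_DROP_INTERVAL_S + 1.0
        holds.append(hold)
        drops.append(n)
        for _ in range(n):
            water += float(rng.uniform(lo, hi))
    return HabituationEntryRecord(
        animal_id=agent.animal_id,
        stage_id=stage_id,
        hold_durations_s=holds,
        drops_per_hold=drops,
        water_ul=water,
        duration_s=duration,
    )


def run_session(
    animal: AnimalState,
    agent: MouseAgent,
    stage: StageSpec,
    config: ProtocolConfig,
    rng: np.random.Generator,
    *,
    day_index: int = 0,
    remaining_budget_min: float = math.inf,
) -> SessionRecord:
    """Run one behavioral session until the termination rule fires.

    Trials accumulate wall-clock time (latency or window, feedback timeout,
    inter-trial interval).  A trial never starts once the maximum-duration
    bound or the cage budget has been reached; running out of cage budget
    may end the session before its minimum duration (``budget_exhausted``).
    Completing the session increments the animal's lifetime count, appends
    to its history, and applies the stage's advancement rule.
    """
    bounds = duration_bounds(animal.lifetime_session_count, config.escalation)
    bias = BiasState()
    trials: list[TrialRecord] = []
    outcomes: list[Outcome] = []
    elapsed = 0.0
    end_reason = "max_duration"
    while True:
        if elapsed >= remaining_budget_min:
            end_reason = "budget_exhausted"
            break
        should_end, reason = session_should_end(elapsed, bounds, outcomes)
        if should_end:
            end_reason = reason or "max_duration"
            break
        engaged = not agent.satiated(animal.water_consumed_today_ul)
        trial = run_trial(
            agent, stage, config, rng, bias,
            animal_id=animal.animal_id,
            trial_index=len(trials),
            session_index=animal.lifetime_session_count,
            day_index=day_index,
            engaged=engaged,
        )
        trials.append(trial)
        outcomes.append(trial.outcome)
        animal.water_consumed_today_ul += trial.reward_ul
        elapsed += trial.duration_s / 60.0

    record = SessionRecord(
        animal_id=animal.animal_id,
        stage_id=stage.stage_id,
        session_index=animal.lifetime_session_count,
        day_index=day_index,
        min_duration_min=bounds[0],
        max_duration_min=bounds[1],
        actual_duration_min=elapsed,
        trials=trials,
        end_reason=end_reason,
    )
    animal.lifetime_session_count += 1
    animal.session_history.append(record)
    stages = config.stages_for(animal.task)
    if animal.task_stage_index < len(stages) - 1 and evaluate_advancement(
        animal, stage.advancement
    ):
        animal.task_stage_index += 1
    return record


def run_day(
    cage: CageState,
    agents: dict[str, MouseAgent],
    config: ProtocolConfig,
    rngs: dict[str, np.random.Generator],
    day_index: int = 0,
) -> DayRecord:
    """Simulate one day of voluntary cage access to the tunnel.

    Animals propose tunnel entries as independent Poisson processes; access
    is serialized (one animal in the tunnel at a time).  Each HF4 entry
    earns a body-beam entry drop, passes the RFID gate, attempts fixation
    (which may be aborted), and then chains one or more sessions.  HF2/HF3
    animals perform habituation visits instead.  The day ends when the cage
    budget is exhausted or every animal is satiated.
    """
    if not cage.animals:
        raise InvalidParameterError("cage has no animals")
    budget = cage.daily_budget_min
    for a in cage.animals:
        a.water_consumed_today_ul = 0.0
    lo, hi = config.reward_volume_ul_range

    t = 0.0
    next_entry: dict[str, float] = {}
    for a in cage.animals:
        next_entry[a.animal_id] = agents[a.animal_id].next_entry_delay_min(rngs[a.animal_id])

    sessions: list[SessionRecord] = []
    hab_entries: list[HabituationEntryRecord] = []
    per_animal = {
        a.animal_id: {"n_sessions": 0, "fixation_min": 0.0, "n_trials": 0, "water_ul": 0.0}
        for a in cage.animals
    }

    def active(a: AnimalState) -> bool:
        return (a.habituation_stage in ("HF2", "HF3", "HF4")
                and not agents[a.animal_id].satiated(a.water_consumed_today_ul))

    while t < budget:
        candidates = [a for a in cage.animals if active(a)]
        if not candidates:
            break
        animal = min(candidates, key=lambda a: (next_entry[a.animal_id], a.animal_id))
        agent = agents[animal.animal_id]
        rng = rngs[animal.animal_id]
        t = max(t, next_entry[animal.animal_id])
        if t >= budget:
            break
        summary = per_animal[animal.animal_id]

        # tunnel entry: body-beam break dispenses one attractant drop
        t += ENTRY_TRANSIT_MIN
        if config.entry_reward:
            drop = float(rng.uniform(lo, hi))
            animal.water_consumed_today_ul += drop
            summary["water_ul"] += drop
        # RFID identification gate: fixation proceeds only once the ID is read

        if animal.habituation_stage in ("HF2", "HF3"):
            rec = run_habituation_entry(agent, animal.habituation_stage, config, rng)
            t += rec.duration_s / 60.0
            animal.water_consumed_today_ul += rec.water_ul
            summary["water_ul"] += rec.water_ul
            summary["fixation_min"] += rec.duration_s / 60.0
            hab_entries.append(rec)
        else:  # HF4: chain behavioral sessions within one entry
            while t < budget:
                attempt_min = float(rng.uniform(*FIXATION_ATTEMPT_S)) / 60.0
                t += attempt_min
                summary["fixation_min"] += attempt_min
                if agent.aborts_fixation(rng) or t >= budget:
                    break
                stage = animal.current_stage(config)
                water_before = animal.water_consumed_today_ul
                srec = run_session(
                    animal, agent, stage, config, rng,
                    day_index=day_index, remaining_budget_min=budget - t,
                )
                t += srec.actual_duration_min
                sessions.append(srec)
                summary["n_sessions"] += 1
                summary["fixation_min"] += srec.actual_duration_min
                summary["n_trials"] += srec.n_trials
                summary["water_ul"] += animal.water_consumed_today_ul - water_before
                if agent.satiated(animal.water_consumed_today_ul):
                    break
                if not agent.chains_again(rng):
                    break
        next_entry[animal.animal_id] = t + agent.next_entry_delay_min(rng)

    # scripted habituation-day progression
    for a in cage.animals:
        if a.habituation_stage != "HF4":
            a.days_in_habituation_stage += 1
            idx = ("HF1", "HF2", "HF3").index(a.habituation_stage)
            if a.days_in_habituation_stage >= config.habituation_days[idx]:
                a.habituation_stage = ("HF2", "HF3", "HF4")[idx]
                a.days_in_habituation_stage = 0

    cage.elapsed_min = min(t, budget)
    return DayRecord(
        day_index=day_index,
        budget_min=budget,
        elapsed_min=cage.elapsed_min,
        sessions=sessions,
        habituation_entries=hab_entries,
        per_animal=per_animal,
    )


# --- cohort driver ---------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything a multi-day cohort simulation produced."""

    config: ProtocolConfig
    cage: CageState
    agents: dict[str, MouseAgent]
    days: list[DayRecord]

    @property
    def sessions(self) -> list[SessionRecord]:
        return [s for d in self.days for s in d.sessions]

    @property
    def trials(self) -> list[TrialRecord]:
        return [t for s in self.sessions for t in s.trials]


def animal_rngs(seed: int, animal_ids: Sequence[str]) -> dict[str, np.random.Generator]:
    """Deterministic per-animal random substreams from one root seed.

    Stream i is ``PCG64(SeedSequence([seed, i]))``; the cohort-generation
    stream uses spawn key ``[seed, 2**20]``.
    """
    return {
        aid: np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, i])))
        for i, aid in enumerate(animal_ids)
    }


def cohort_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 2**20])))


def simulate_cohort(
    config: ProtocolConfig,
    n_animals: int,
    n_days: int,
    seed: int,
    task: TaskKind = TaskKind.DISCRIMINATION,
    start_at: str = "HF4",
    cohort_params=None,
) -> SimulationResult:
    """Simulate a cage of synthetic mice for ``n_days`` of voluntary training.

    By default animals start the behavioral task directly (habituation
    pre-completed); ``start_at='HF1'`` runs the scripted habituation days
    first.  Identical (seed, config) pairs reproduce identical results.
    """
    from .mouse_agent import make_default_cohort

    ids = [f"RFID{i:03d}" for i in range(n_animals)]
    if cohort_params is None:
        cohort_params = make_default_cohort(n_animals, cohort_rng(seed))
    agents = {
        aid: MouseAgent(p, animal_id=aid, mapping=config.mapping)
        for aid, p in zip(ids, cohort_params)
    }
    animals = [
        AnimalState(animal_id=aid, task=task, habituation_stage=start_at)
        for aid in ids
    ]
    cage = CageState(animals=animals, budget_min_per_mouse=config.budget_min_per_mouse)
    rngs = animal_rngs(seed, ids)
    days = [
        run_day(cage, agents, config, rngs, day_index=d) for d in range(n_days)
    ]
    return SimulationResult(config=config, cage=cage, agents=agents, days=days)
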
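"""Single-trial execution: stimulus sampling, wheel-response classification,
adjudication and feedback.

A trial starts at tone onset.  The animal reports by turning a wheel; the
first time (after the grace period) the cumulative wheel angle departs from
its grace-end reference by at least the stage's decision threshold defines
the choice and its latency.  Correct choices dispense one water drop and
truncate the tone; incorrect choices trigger a silent timeout and, in later
stages, brief tactile (vibration) feedback; no threshold crossing within the
response window is a miss.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Sequence

import numpy as np

from .protocol import (
    ProtocolConfig,
    StageSpec,
    TaskKind,
    ToneStimulus,
    tone_category,
    ToneCategory,
    InfeasibleConfigurationError,
)


class MalformedInputError(ValueError):
    """Input data violates a structural requirement (e.g. unordered trace)."""


class Direction(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    EITHER = "either"
    ANY_RESPONSE = "any_response"
    NONE = "none"


class Outcome(str, Enum):
    HIT = "hit"
    INCORRECT = "incorrect"
    MISS = "miss"


@dataclass(frozen=True)
class WheelTrace:
    """Cumulative wheel angle over time, sampled from tone onset (t=0).

    Positive angles are rightward turns from the mouse's perspective.
    """

    times_s: tuple[float, ...]
    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        t, a = self.times_s, self.angles_deg
        if len(t) != len(a) or not t:
            raise MalformedInputError("trace needs equal, nonzero numbers of times and angles")
        if t[0] < 0:
            raise MalformedInputError("trace must start at or after tone onset (t=0)")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise MalformedInputError("trace times must be strictly increasing")
        if any(not math.isfinite(x) for x in a):
            raise MalformedInputError("trace angles must be finite")

    def angle_at(self, t: float) -> float:
        """Piecewise-linear interpolation; clamped at the end samples."""
        return float(np.interp(t, self.times_s, self.angles_deg))


@dataclass
class BiasState:
    """Carries the previous stimulus/outcome for the repeat-after-error rule."""

    last_stimulus: ToneStimulus | None = None
    last_outcome: Outcome | None = None

    def observe(self, stimulus: ToneStimulus, outcome: Outcome) -> None:
        self.last_stimulus = stimulus
        self.last_outcome = outcome

    def reset(self) -> None:
        self.last_stimulus = None
        self.last_outcome = None


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus-response-outcome event with the feedback applied."""

    animal_id: str
    stage_id: str
    task: TaskKind
    stimulus: ToneStimulus
    required_direction: Direction
    choice: Direction
    outcome: Outcome
    latency_s: float | None
    tone_truncated_at_s: float | None
    reward_ul: float
    timeout_applied_s: float
    tactile_applied_s: float
    bias_corrected: bool
    trial_index: int = 0
    session_index: int = 0
    day_index: int = 0
    duration_s: float = 0.0  # wall-clock time the trial occupied (incl. ITI)


def required_direction(frequency_hz: float, boundary_hz: float, mapping: str = "default") -> Direction:
    """Rewarded turn direction for a discrimination tone.

    Under the default mapping low tones (< boundary) require a rightward
    turn and high tones a leftward turn; the boundary tone is rewarded for
    either direction.  The reversed mapping swaps left and right.
    """
    if frequency_hz <= 0:
        raise MalformedInputError("frequency_hz must be positive")
    if frequency_hz == boundary_hz:
        return Direction.EITHER
    low = frequency_hz < boundary_hz
    if mapping == "reversed":
        low = not low
    return Direction.RIGHT if low else Direction.LEFT


def sample_stimulus(stage: StageSpec, bias: BiasState, rng: np.random.Generator) -> ToneStimulus:
    """Draw the next tone, honoring the stage's bias-correction rule.

    With bias correction on, the previous stimulus is repeated verbatim
    until the animal scores a hit.  Otherwise the frequency is drawn from
    the stage's presentation probabilities; detection stages additionally
    draw the sound level uniformly from the stage's level set, independent
    of frequency.
    """
    if not stage.tone_frequencies_hz:
        raise InfeasibleConfigurationError(f"stage {stage.stage_id} has no tones")
    if stage.bias_correction and bias.last_outcome is not None and bias.last_outcome is not Outcome.HIT:
        assert bias.last_stimulus is not None
        return bias.last_stimulus
    u = rng.random()
    idx = int(np.searchsorted(stage.cumulative_probabilities, u, side="right"))
    idx = min(idx, len(stage.tone_frequencies_hz) - 1)
    f = stage.tone_frequencies_hz[idx]
    if stage.task_kind is TaskKind.DETECTION:
        level = stage.sound_levels_db[int(rng.integers(len(stage.sound_levels_db)))]
        cat = ToneCategory.DETECTION
    else:
        level = stage.sound_levels_db[0]
        cat = tone_category(f, stage.boundary_hz) if stage.boundary_hz else ToneCategory.DETECTION
    return ToneStimulus(
        frequency_hz=f,
        level_db_spl=level,
        duration_s=stage.tone_duration_s,
        am_rate_hz=stage.am_rate_hz,
        category=cat,
    )


def classify_wheel_response(trace: WheelTrace, stage: StageSpec) -> tuple[Direction, float | None]:
    """First threshold crossing of the wheel after the grace period.

    Wheel motion during the grace period is discounted: the angle reference
    is re-zeroed at the end of the grace period, and the first sample time
    in (grace, window] whose displacement from that reference reaches the
    decision threshold (exact equality counts) defines the choice and
    latency.  No crossing within the window returns (none, None).
    """
    grace = stage.grace_period_s
    window = stage.response_window_s
    thr = stage.decision_threshold_deg
    ref = trace.angle_at(grace)
    for t, a in zip(trace.times_s, trace.angles_deg):
        if t <= grace:
            continue
        if t > window:
            break
        d = a - ref
        if d >= thr:
            return Direction.RIGHT, t
        if d <= -thr:
            return Direction.LEFT, t
    return Direction.NONE, None


def adjudicate(choice: Direction, required: Direction, task_kind: TaskKind) -> Outcome:
    """Map a choice to hit / incorrect / miss.

    Detection trials are hits for any response and misses otherwise;
    incorrect is impossible.  Discrimination trials are hits when the
    choice matches the required direction (or the requirement is 'either').
    """
    if choice is Direction.NONE:
        return Outcome.MISS
    if task_kind is TaskKind.DETECTION or required is Direction.ANY_RESPONSE:
        return Outcome.HIT
    if required is Direction.EITHER or choice is required:
        return Outcome.HIT
    return Outcome.INCORRECT


def run_trial(
    agent,
    stage: StageSpec,
    config: ProtocolConfig,
    rng: np.random.Generator,
    bias: BiasState,
    *,
    animal_id: str = "mouse",
    trial_index: int = 0,
    session_index: int = 0,
    day_index: int = 0,
    engaged: bool = True,
) -> TrialRecord:
    """Run one complete trial: sample, respond, classify, adjudicate, feed back.

    A choice made before tone offset truncates the tone at the choice
    latency.  Hits dispense one water drop with volume drawn uniformly from
    the configured range; incorrect choices apply the stage's timeout and
    tactile feedback.  The wall-clock duration charged to the session is
    latency (or the full window for misses) plus any timeout plus the
    inter-trial interval.
    """
    stimulus = sample_stimulus(stage, bias, rng)
    was_repeat = (stage.bias_correction and bias.last_outcome is not None
                  and bias.last_outcome is not Outcome.HIT)

    if stage.task_kind is TaskKind.DETECTION:
        req = Direction.ANY_RESPONSE
    else:
        req = required_direction(stimulus.frequency_hz, stage.boundary_hz or config.boundary_hz,
                                 config.mapping)

    trace = agent.wheel_trace(stimulus, stage, rng, engaged=engaged)
    choice, latency = classify_wheel_response(trace, stage)
    outcome = adjudicate(choice, req, stage.task_kind)

    reward = 0.0
    timeout = 0.0
    tactile = 0.0
    if outcome is Outcome.HIT:
        lo, hi = config.reward_volume_ul_range
        reward = float(rng.uniform(lo, hi))
    elif outcome is Outcome.INCORRECT:
        timeout = stage.timeout_s
        tactile = stage.tactile_s

    truncated = latency if (latency is not None and latency < stage.tone_duration_s) else None
    response_time = latency if latency is not None else stage.response_window_s
    duration = response_time + timeout + config.inter_trial_interval_s

    bias.observe(stimulus, outcome)
    return TrialRecord(
        animal_id=animal_id,
        stage_id=stage.stage_id,
        task=stage.task_kind,
        stimulus=stimulus,
        required_direction=req,
        choice=choice,
        outcome=outcome,
        latency_s=latency,
        tone_truncated_at_s=truncated,
        reward_ul=reward,
        timeout_applied_s=timeout,
        tactile_applied_s=tactile,
        bias_corrected=was_repeat,
        trial_index=trial_index,
        session_index=session_index,
        day_index=day_index,
        duration_s=duration,
    )


# --- trial-log CSV ---------------------------------------------------------

TRIAL_LOG_COLUMNS = (
    "day", "animal_id", "session_index", "trial_index", "stage_id", "task",
    "frequency_hz", "level_db", "required_direction", "choice", "outcome",
    "latency_s", "tone_truncated_at_s", "reward_ul", "timeout_s", "tactile_s",
    "bias_corrected",
)


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_trial_log(records: Iterable[TrialRecord], fh: IO[str]) -> None:
    """Serialize trials as CSV (UTF-8, LF, full float precision)."""
    w = csv.writer(fh, lineterminator="\n")
    w.writerow(TRIAL_LOG_COLUMNS)
    for r in records:
        w.writerow((
            r.day_index, r.animal_id, r.session_index, r.trial_index,
            r.stage_id, r.task.value, _fmt(r.stimulus.frequency_hz),
            _fmt(r.stimulus.level_db_spl), r.required_direction.value,
            r.choice.value, r.outcome.value, _fmt(r.latency_s),
            _fmt(r.tone_truncated_at_s), _fmt(r.reward_ul),
            _fmt(r.timeout_applied_s), _fmt(r.tactile_applied_s),
            int(r.bias_corrected),
        ))


def read_trial_log(fh: IO[str], config: ProtocolConfig | None = None) -> list[TrialRecord]:
    """Parse a trial-log CSV back into TrialRecord objects.

    Stimulus duration/AM-rate/category are reconstructed from the stage when
    a protocol is supplied, else from task-level defaults.
    """
    reader = csv.DictReader(fh)
    out = []
    for row in reader:
        task = TaskKind(row["task"])
        freq = float(row["frequency_hz"])
        if config is not None:
            stage = config.stage(row["stage_id"])
            dur, am = stage.tone_duration_s, stage.am_rate_hz
            cat = (tone_category(freq, stage.boundary_hz) if stage.boundary_hz
                   else ToneCategory.DETECTION)
        else:
            dur = 2.0 if task is TaskKind.DISCRIMINATION else 0.2
            am = 10.0 if task is TaskKind.DISCRIMINATION else 0.0
            cat = ToneCategory.DETECTION
        lat = float(row["latency_s"]) if row["latency_s"] else None
        trunc = float(row["tone_truncated_at_s"]) if row["tone_truncated_at_s"] else None
        response_time = lat if lat is not None else (
            4.0 if task is TaskKind.DISCRIMINATION else 0.5)
        out.append(TrialRecord(
            animal_id=row["animal_id"],
            stage_id=row["stage_id"],
            task=task,
            stimulus=ToneStimulus(freq, float(row["level_db"]), dur, am, cat),
            required_direction=Direction(row["required_direction"]),
            choice=Direction(row["choice"]),
            outcome=Outcome(row["outcome"]),
            latency_s=lat,
            tone_truncated_at_s=trunc,
            reward_ul=float(row["reward_ul"]),
            timeout_applied_s=float(row["timeout_s"]),
            tactile_applied_s=float(row["tactile_s"]),
            bias_corrected=bool(int(row["bias_corrected"])),
            trial_index=int(row["trial_index"]),
            session_index=int(row["session_index"]),
            day_index=int(row["day"]),
        ))
    return out
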
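"""Training-protocol definition for automated voluntary head-fixation.

The protocol trains water-restricted, RFID-tagged mice living in a homecage
attached to a head-fixation tunnel.  Four habituation stages (HF1-HF4)
accustom the animal to the tunnel and to head fixation; the behavioral task
itself is either a two-alternative forced-choice (2AFC) frequency
discrimination around a 20 kHz category boundary (stages D1-D5) or a tone
detection task across sound levels (stages T1-T3).

Stage parameterizations are *derived* from a small set of rules (octave
offsets from the boundary, an inner-tone presentation probability, a
tones-per-octave density) rather than hard-coded per stage, so the encoded
tables can be reconstructed and audited.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from fractions import Fraction
from functools import cached_property
from typing import Sequence


class ProtocolError(ValueError):
    """Base class for protocol construction errors."""


class InvalidParameterError(ProtocolError):
    """A parameter is out of its valid domain."""


class InfeasibleConfigurationError(ProtocolError):
    """The requested configuration cannot satisfy the protocol's rules."""


class TaskKind(str, Enum):
    HABITUATION = "habituation"
    DISCRIMINATION = "discrimination"
    DETECTION = "detection"


class ToneCategory(str, Enum):
    LOW = "low"
    HIGH = "high"
    BOUNDARY = "boundary"
    DETECTION = "detection"


#: Octave offsets (re the 20 kHz boundary) of the full discrimination set.
FULL_DISCRIMINATION_OFFSETS: tuple[float, ...] = (
    -1.0, -0.5, -0.25, -0.125, -0.0625, 0.0, 0.0625, 0.125, 0.25, 0.5, 1.0,
)

#: |octave offset| at and beyond which a discrimination tone counts as an
#: "edge" tone (10, 14.1, 28.3, 40 kHz).  Edge tones share the probability
#: mass left over after every inner tone receives ``inner_probability``.
EDGE_OFFSET_OCTAVES = 0.5

#: Octave offsets presented in each discrimination stage (Table-driven).
STAGE_OFFSETS: dict[str, tuple[float, ...]] = {
    "D1": (-1.0, 1.0),
    "D2": (-1.0, -0.5, 0.5, 1.0),
    "D3": (-1.0, -0.5, -0.25, 0.25, 0.5, 1.0),
    "D4": (-1.0, -0.5, -0.25, -0.125, 0.125, 0.25, 0.5, 1.0),
    "D5": FULL_DISCRIMINATION_OFFSETS,
}

HABITUATION_STAGES = ("HF1", "HF2", "HF3", "HF4")


def tone_category(frequency_hz: float, boundary_hz: float) -> ToneCategory:
    if frequency_hz < boundary_hz:
        return ToneCategory.LOW
    if frequency_hz > boundary_hz:
        return ToneCategory.HIGH
    return ToneCategory.BOUNDARY


@dataclass(frozen=True)
class ToneStimulus:
    """One tone: frequency, sound level, duration, AM rate and category."""

    frequency_hz: float
    level_db_spl: float
    duration_s: float
    am_rate_hz: float = 0.0
    category: ToneCategory = ToneCategory.DETECTION

    def __post_init__(self) -> None:
        if not (self.frequency_hz > 0 and math.isfinite(self.frequency_hz)):
            raise InvalidParameterError(f"frequency_hz must be positive, got {self.frequency_hz}")
        if not (0.0 <= self.level_db_spl <= 120.0):
            raise InvalidParameterError(f"level_db_spl outside [0, 120]: {self.level_db_spl}")
        if not self.duration_s > 0:
            raise InvalidParameterError(f"duration_s must be positive, got {self.duration_s}")

    def octave_offset(self, boundary_hz: float) -> float:
        """log2(f / boundary): position on the octave axis re the boundary."""
        return math.log2(self.frequency_hz / boundary_hz)


@dataclass(frozen=True)
class AdvancementCriterion:
    """Rule deciding when an animal graduates from a stage.

    ``window_hitrate``: a hit rate of at least ``hitrate_min`` over some
    contiguous run of exactly ``window_size`` trials within one session.
    ``session_count``: at least ``sessions_required`` of the most recent
    ``lookback_sessions`` sessions contain at least ``trials_min`` trials.
    ``none``: terminal stage.
    """

    kind: str = "none"
    window_size: int = 50
    hitrate_min: float = 0.8
    trials_min: int = 50
    sessions_required: int = 5
    lookback_sessions: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("window_hitrate", "session_count", "none"):
            raise InvalidParameterError(f"unknown advancement kind {self.kind!r}")
        if not (0.0 < self.hitrate_min <= 1.0):
            raise InvalidParameterError("hitrate_min must be in (0, 1]")
        if self.window_size < 1:
            raise InvalidParameterError("window_size must be >= 1")
        if self.sessions_required > self.lookback_sessions:
            raise InvalidParameterError("sessions_required cannot exceed lookback_sessions")


@dataclass(frozen=True)
class StageSpec:
    """Full parameterization of one training stage."""

    stage_id: str
    task_kind: TaskKind
    tone_frequencies_hz: tuple[float, ...] = ()
    presentation_probabilities: tuple[float, ...] = ()
    sound_levels_db: tuple[float, ...] = (70.0,)
    decision_threshold_deg: float = 5.0
    grace_period_s: float = 0.0
    response_window_s: float = 4.0
    tone_duration_s: float = 2.0
    am_rate_hz: float = 0.0
    timeout_s: float = 0.0
    tactile_s: float = 0.0
    bias_correction: bool = False
    advancement: AdvancementCriterion = field(default_factory=AdvancementCriterion)
    boundary_hz: float | None = None

    def __post_init__(self) -> None:
        if self.task_kind is not TaskKind.HABITUATION:
            if not self.decision_threshold_deg > 0:
                raise InvalidParameterError("decision_threshold_deg must be positive")
            probs = self.presentation_probabilities
            if any(p < 0 for p in probs):
                raise InvalidParameterError("presentation probabilities must be nonnegative")
            if probs and abs(sum(probs) - 1.0) > 1e-9:
                raise InvalidParameterError(f"probabilities sum to {sum(probs)!r}, not 1")
            if len(probs) != len(self.tone_frequencies_hz):
                raise InvalidParameterError("one probability per tone required")
        if self.timeout_s < 0 or self.tactile_s < 0:
            raise InvalidParameterError("timeout_s and tactile_s must be >= 0")

    @cached_property
    def cumulative_probabilities(self) -> "np.ndarray":
        import numpy as np

        out = np.cumsum(self.presentation_probabilities)
        if out.size:
            out[-1] = max(out[-1], 1.0)  # guard float round-down for the last bin
        return out


@dataclass(frozen=True)
class EscalationSchedule:
    """Session-duration escalation during HF4.

    Sessions start with minimum and maximum duration both at 0.5 min; for
    every ``sessions_per_increment`` completed sessions the minimum grows by
    ``inc_min_min`` and the maximum by ``inc_max_min``, capped at 3 and
    30 min respectively.
    """

    start_min_min: float = 0.5
    start_max_min: float = 0.5
    inc_min_min: float = 0.25
    inc_max_min: float = 0.5
    sessions_per_increment: int = 5
    cap_min_min: float = 3.0
    cap_max_min: float = 30.0

    def __post_init__(self) -> None:
        vals = (self.start_min_min, self.start_max_min, self.inc_min_min,
                self.inc_max_min, self.sessions_per_increment,
                self.cap_min_min, self.cap_max_min)
        if any(v <= 0 for v in vals):
            raise InvalidParameterError("all escalation parameters must be positive")
        if self.cap_min_min > self.cap_max_min:
            raise InvalidParameterError("cap_min_min cannot exceed cap_max_min")
        if self.start_min_min > self.cap_min_min or self.start_max_min > self.cap_max_min:
            raise InvalidParameterError("start durations cannot exceed their caps")


@dataclass(frozen=True)
class ProtocolConfig:
    """Whole-protocol configuration: boundary, stages, budgets, escalation."""

    boundary_hz: float = 20000.0
    mapping: str = "default"  # 'default': low tone -> right turn; 'reversed' swaps
    reward_volume_ul_range: tuple[float, float] = (5.0, 7.0)
    budget_min_per_mouse: float = 40.0
    inter_trial_interval_s: float = 1.0
    entry_reward: bool = True
    escalation: EscalationSchedule = field(default_factory=EscalationSchedule)
    habituation_stages: tuple[StageSpec, ...] = ()
    discrimination_stages: tuple[StageSpec, ...] = ()
    detection_stages: tuple[StageSpec, ...] = ()
    #: simulated days spent in each scripted habituation stage
    habituation_days: tuple[int, ...] = (4, 2, 3)  # HF1, HF2, HF3

    def __post_init__(self) -> None:
        if self.boundary_hz <= 0:
            raise InvalidParameterError("boundary_hz must be positive")
        if self.budget_min_per_mouse <= 0:
            raise InvalidParameterError("budget_min_per_mouse must be positive")
        lo, hi = self.reward_volume_ul_range
        if lo > hi:
            raise InvalidParameterError("reward volume range low > high")
        if self.mapping not in ("default", "reversed"):
            raise InvalidParameterError(f"unknown mapping {self.mapping!r}")

    def stages_for(self, task: TaskKind) -> tuple[StageSpec, ...]:
        if task is TaskKind.DISCRIMINATION:
            return self.discrimination_stages
        if task is TaskKind.DETECTION:
            return self.detection_stages
        return self.habituation_stages

    def stage(self, stage_id: str) -> StageSpec:
        for group in (self.habituation_stages, self.discrimination_stages,
                      self.detection_stages):
            for s in group:
                if s.stage_id == stage_id:
                    return s
        raise KeyError(stage_id)


def build_discrimination_tone_set(
    boundary_hz: float, octave_offsets: Sequence[float]
) -> list[float]:
    """Frequencies at ``boundary_hz * 2**offset`` for each octave offset.

    Offsets symmetric about zero yield frequency pairs whose product is
    ``boundary_hz ** 2`` (log-symmetry about the category boundary).
    """
    if boundary_hz <= 0:
        raise InvalidParameterError("boundary_hz must be positive")
    for o in octave_offsets:
        if not math.isfinite(o):
            raise InvalidParameterError(f"non-finite octave offset: {o}")
    return [boundary_hz * 2.0 ** o for o in octave_offsets]


def build_detection_tone_set(
    center_hz: float, half_span_octaves: float, tones_per_octave: int
) -> list[float]:
    """Geometrically spaced tones spanning ±``half_span_octaves`` around a center.

    The step between adjacent tones is ``2 ** (1 / tones_per_octave)``; the
    total count is ``2 * half_span_octaves * tones_per_octave + 1`` and must
    come out integral.
    """
    if half_span_octaves <= 0:
        raise InvalidParameterError("half_span_octaves must be positive")
    if tones_per_octave < 1:
        raise InvalidParameterError("tones_per_octave must be >= 1")
    n_steps = 2.0 * half_span_octaves * tones_per_octave
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidParameterError(
            f"span {half_span_octaves} oct at {tones_per_octave}/oct does not "
            "produce an integer tone count"
        )
    n_steps = round(n_steps)
    return [
        center_hz * 2.0 ** (-half_span_octaves + k / tones_per_octave)
        for k in range(n_steps + 1)
    ]


def resolve_probabilities(
    octave_offsets: Sequence[float],
    inner_probability: Fraction | float = Fraction(1, 20),
) -> list[Fraction]:
    """Presentation probabilities for a discrimination tone set.

    Every inner tone (|offset| < 0.5 octave) is presented with
    ``inner_probability``; the edge tones split the remaining mass equally.
    Stages with no inner tones therefore come out uniform.  Exact rational
    arithmetic keeps the tabulated values (0.225, 0.2, 0.1625) exact.
    """
    if not octave_offsets:
        raise InfeasibleConfigurationError("stage must have at least one tone")
    p_inner = (inner_probability if isinstance(inner_probability, Fraction)
               else Fraction(inner_probability).limit_denominator(10**9))
    inner = [abs(o) < EDGE_OFFSET_OCTAVES for o in octave_offsets]
    n_inner = sum(inner)
    n_edge = len(octave_offsets) - n_inner
    remaining = 1 - n_inner * p_inner
    if n_edge == 0:
        raise InfeasibleConfigurationError("stage has no edge tones to absorb probability mass")
    if remaining <= 0:
        raise InfeasibleConfigurationError(
            f"inner probability {p_inner} x {n_inner} tones leaves no mass for edge tones"
        )
    p_edge = remaining / n_edge
    return [p_inner if is_inner else p_edge for is_inner in inner]


def resolve_stage_probabilities(
    stage_id: str, inner_probability: Fraction | float = Fraction(1, 20)
) -> list[Fraction]:
    """Presentation probabilities for a default discrimination stage by id."""
    try:
        offsets = STAGE_OFFSETS[stage_id]
    except KeyError:
        raise InvalidParameterError(f"unknown discrimination stage {stage_id!r}") from None
    return resolve_probabilities(offsets, inner_probability)


def _discrimination_stage(
    stage_id: str,
    boundary_hz: float,
    *,
    decision_threshold_deg: float,
    timeout_s: float,
    tactile_s: float,
    bias_correction: bool,
    advancement: AdvancementCriterion,
    inner_probability: Fraction = Fraction(1, 20),
) -> StageSpec:
    offsets = STAGE_OFFSETS[stage_id]
    freqs = build_discrimination_tone_set(boundary_hz, offsets)
    probs = resolve_probabilities(offsets, inner_probability)
    return StageSpec(
        stage_id=stage_id,
        task_kind=TaskKind.DISCRIMINATION,
        tone_frequencies_hz=tuple(freqs),
        presentation_probabilities=tuple(float(p) for p in probs),
        sound_levels_db=(70.0,),
        decision_threshold_deg=decision_threshold_deg,
        grace_period_s=0.1,
        response_window_s=4.0,
        tone_duration_s=2.0,
        am_rate_hz=10.0,
        timeout_s=timeout_s,
        tactile_s=tactile_s,
        bias_correction=bias_correction,
        advancement=advancement,
        boundary_hz=boundary_hz,
    )


def _detection_stage(
    stage_id: str,
    frequencies: Sequence[float],
    levels_db: Sequence[float],
    *,
    decision_threshold_deg: float,
    advancement: AdvancementCriterion,
) -> StageSpec:
    n = len(frequencies)
    return StageSpec(
        stage_id=stage_id,
        task_kind=TaskKind.DETECTION,
        tone_frequencies_hz=tuple(frequencies),
        presentation_probabilities=tuple(1.0 / n for _ in range(n)),
        sound_levels_db=tuple(levels_db),
        decision_threshold_deg=decision_threshold_deg,
        grace_period_s=0.0,
        response_window_s=0.5,
        tone_duration_s=0.2,
        am_rate_hz=0.0,
        timeout_s=0.0,
        tactile_s=0.0,
        bias_correction=False,
        advancement=advancement,
    )


def default_protocol(boundary_hz: float = 20000.0, mapping: str = "default") -> ProtocolConfig:
    """The shipped protocol: HF1-HF4, discrimination D1-D5, detection T1-T3."""
    window = AdvancementCriterion(kind="window_hitrate", window_size=50, hitrate_min=0.8)
    by_sessions = AdvancementCriterion(
        kind="session_count", trials_min=50, sessions_required=5, lookback_sessions=10
    )
    terminal = AdvancementCriterion(kind="none")

    disc = (
        _discrimination_stage("D1", boundary_hz, decision_threshold_deg=5.0,
                              timeout_s=4.0, tactile_s=0.0, bias_correction=True,
                              advancement=window),
        _discrimination_stage("D2", boundary_hz, decision_threshold_deg=10.0,
                              timeout_s=4.0, tactile_s=0.2, bias_correction=True,
                              advancement=window),
        _discrimination_stage("D3", boundary_hz, decision_threshold_deg=10.0,
                              timeout_s=6.0, tactile_s=0.2, bias_correction=False,
                              advancement=by_sessions),
        _discrimination_stage("D4", boundary_hz, decision_threshold_deg=10.0,
                              timeout_s=8.0, tactile_s=0.2, bias_correction=False,
                              advancement=by_sessions),
        _discrimination_stage("D5", boundary_hz, decision_threshold_deg=10.0,
                              timeout_s=8.0, tactile_s=0.2, bias_correction=False,
                              advancement=terminal),
    )

    det_freqs = build_detection_tone_set(boundary_hz, 1.5, 5)
    det = (
        _detection_stage("T1", det_freqs, (70.0,), decision_threshold_deg=5.0,
                         advancement=window),
        _detection_stage("T2", det_freqs, (70.0, 60.0, 50.0, 40.0),
                         decision_threshold_deg=15.0, advancement=by_sessions),
        _detection_stage("T3", det_freqs, (70.0, 60.0, 50.0, 40.0, 30.0, 20.0, 10.0),
                         decision_threshold_deg=15.0, advancement=terminal),
    )

    hab = tuple(
        StageSpec(stage_id=sid, task_kind=TaskKind.HABITUATION,
                  decision_threshold_deg=1.0, advancement=AdvancementCriterion(kind="none"))
        for sid in HABITUATION_STAGES
    )

    return ProtocolConfig(
        boundary_hz=boundary_hz,
        mapping=mapping,
        habituation_stages=hab,
        discrimination_stages=disc,
        detection_stages=det,
    )


# --- JSON serialization ----------------------------------------------------

def _stage_to_dict(s: StageSpec) -> dict:
    d = asdict(s)
    d["task_kind"] = s.task_kind.value
    return d


def protocol_to_json(config: ProtocolConfig) -> str:
    doc = {
        "boundary_hz": config.boundary_hz,
        "mapping": config.mapping,
        "reward_volume_ul_range": list(config.reward_volume_ul_range),
        "budget_min_per_mouse": config.budget_min_per_mouse,
        "inter_trial_interval_s": config.inter_trial_interval_s,
        "entry_reward": config.entry_reward,
        "escalation": asdict(config.escalation),
        "habituation_days": list(config.habituation_days),
        "stages": [_stage_to_dict(s)
                   for group in (config.habituation_stages,
                                 config.discrimination_stages,
                                 config.detection_stages)
                   for s in group],
    }
    return json.dumps(doc, indent=2) + "\n"


def _stage_from_dict(d: dict) -> StageSpec:
    d = dict(d)
    d["task_kind"] = TaskKind(d["task_kind"])
    d["advancement"] = AdvancementCriterion(**d["advancement"])
    for key in ("tone_frequencies_hz", "presentation_probabilities", "sound_levels_db"):
        d[key] = tuple(d[key])
    return StageSpec(**d)


def protocol_from_json(text: str) -> ProtocolConfig:
    doc = json.loads(text)
    stages = [_stage_from_dict(d) for d in doc["stages"]]
    groups: dict[TaskKind, list[StageSpec]] = {k: [] for k in TaskKind}
    for s in stages:
        groups[s.task_kind].append(s)
    return ProtocolConfig(
        boundary_hz=doc["boundary_hz"],
        mapping=doc["mapping"],
        reward_volume_ul_range=tuple(doc["reward_volume_ul_range"]),
        budget_min_per_mouse=doc["budget_min_per_mouse"],
        inter_trial_interval_s=doc["inter_trial_interval_s"],
        entry_reward=doc["entry_reward"],
        escalation=EscalationSchedule(**doc["escalation"]),
        habituation_days=tuple(doc["habituation_days"]),
        habituation_stages=tuple(groups[TaskKind.HABITUATION]),
        discrimination_stages=tuple(groups[TaskKind.DISCRIMINATION]),
        detection_stages=tuple(groups[TaskKind.DETECTION]),
    )
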
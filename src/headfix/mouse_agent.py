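"""Generative synthetic mouse: psychometric choice behavior, level-dependent
tone detection, response latencies, and homecage engagement.

The agent is a stationary stochastic model with known ground-truth
parameters, so the training engine and every analysis routine can be tested
against the generating process:

* discrimination choices follow a logistic psychometric function of the
  tone's octave offset from the category boundary, with a lapse rate and an
  optional side bias expressed during lapses;
* detection follows a logistic function of sound level re a frequency-
  dependent threshold curve that is quadratic in log-frequency with its
  minimum at a best frequency (14.1 kHz by default, the region where the
  mouse audiogram is most sensitive);
* hit latency decreases linearly with sound level plus truncated Gaussian
  noise;
* engagement is a Poisson entry process that switches off once the day's
  water target is met, with per-attempt fixation aborts and voluntary
  session chaining within a tunnel entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
import json
from typing import IO

import numpy as np

from .protocol import StageSpec, TaskKind, ToneStimulus, InvalidParameterError
from .trial_engine import Direction, WheelTrace


def _logistic(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth behavioral parameters of one synthetic mouse."""

    # discrimination psychometrics
    disc_pse_octave: float = 0.0        # point of subjective equality (oct re boundary)
    disc_slope_octave: float = 0.15     # psychometric spread (oct)
    lapse: float = 0.06                 # probability of a stimulus-independent choice
    side_bias: float = 0.0              # extra high-side mass during lapses (+/-0.5 max)
    disc_miss_prob: float = 0.12        # probability of not responding at all
    # detection psychoacoustics
    det_best_freq_hz: float = 14142.135623730951   # 20 kHz * 2**-0.5
    det_threshold_db_at_best: float = 30.0
    det_threshold_curvature: float = 15.0          # dB per octave^2 away from best
    det_slope_db: float = 5.0
    guess_rate: float = 0.05            # spontaneous response probability
    # latency model
    lat_base_s: float = 2.2             # discrimination latency intercept (s)
    lat_level_slope_s_per_db: float = -0.003
    lat_sd_s: float = 0.7
    det_lat_base_s: float = 0.38        # detection latency intercept before level term
    det_lat_sd_s: float = 0.05
    # engagement
    entry_rate_per_min: float = 0.6
    abort_prob: float = 0.05
    session_chain_prob: float = 0.85
    daily_water_target_ul: float = 2500.0
    hold_mean_s: float = 6.0            # habituation head-hold duration scale

    def __post_init__(self) -> None:
        for name in ("lapse", "guess_rate", "abort_prob", "disc_miss_prob",
                     "session_chain_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.disc_slope_octave <= 0 or self.det_slope_db <= 0:
            raise InvalidParameterError("psychometric slopes must be positive")
        if self.lat_sd_s < 0 or self.det_lat_sd_s < 0:
            raise InvalidParameterError("latency noise SDs must be >= 0")
        if self.entry_rate_per_min <= 0:
            raise InvalidParameterError("entry_rate_per_min must be positive")

    def detection_threshold_db(self, frequency_hz: float) -> float:
        """U-shaped audiogram: quadratic in octaves away from the best frequency."""
        o = math.log2(frequency_hz / self.det_best_freq_hz)
        return self.det_threshold_db_at_best + self.det_threshold_curvature * o * o


def agent_choice_discrimination(
    params: AgentParams,
    stimulus: ToneStimulus,
    stage: StageSpec,
    rng: np.random.Generator,
) -> tuple[Direction | None, float | None]:
    """Sample a discrimination response: (high-or-low side as a direction, latency).

    Returns (None, None) for a non-response.  The direction returned is in
    *category space* mapped through the stage's boundary under the default
    mapping (low -> right, high -> left); callers needing the reversed
    mapping flip it.
    """
    if rng.random() < params.disc_miss_prob:
        return None, None
    boundary = stage.boundary_hz if stage.boundary_hz else 20000.0
    o = math.log2(stimulus.frequency_hz / boundary)
    if rng.random() < params.lapse:
        p_high = min(1.0, max(0.0, 0.5 + params.side_bias))
    else:
        p_high = _logistic((o - params.disc_pse_octave) / params.disc_slope_octave)
    high = rng.random() < p_high
    lat = params.lat_base_s + params.lat_level_slope_s_per_db * stimulus.level_db_spl
    lat += params.lat_sd_s * rng.standard_normal()
    lo = stage.grace_period_s + 1e-3
    lat = min(max(lat, lo), stage.response_window_s)
    return (Direction.LEFT if high else Direction.RIGHT), lat


def agent_response_detection(
    params: AgentParams,
    stimulus: ToneStimulus,
    rng: np.random.Generator,
    window_s: float = 0.5,
) -> tuple[bool, float | None]:
    """Sample a detection response: whether the agent turned, and when.

    P(respond) = guess + (1 - guess - lapse) * logistic((L - theta(f)) / slope)
    where theta(f) is the agent's audiogram threshold at the tone frequency.
    Latency decreases with sound level and is truncated to (0, window].
    """
    theta = params.detection_threshold_db(stimulus.frequency_hz)
    p = params.guess_rate + (1.0 - params.guess_rate - params.lapse) * _logistic(
        (stimulus.level_db_spl - theta) / params.det_slope_db
    )
    if rng.random() >= p:
        return False, None
    lat = params.det_lat_base_s + params.lat_level_slope_s_per_db * stimulus.level_db_spl
    lat += params.det_lat_sd_s * rng.standard_normal()
    lat = min(max(lat, 1e-3), window_s)
    return True, lat


class MouseAgent:
    """Stateless behavioral model driven by :class:`AgentParams`."""

    def __init__(self, params: AgentParams, animal_id: str = "mouse",
                 mapping: str = "default"):
        self.params = params
        self.animal_id = animal_id
        self.mapping = mapping  # contingency the animal was trained under

    # --- trial-level behavior ---------------------------------------------

    def wheel_trace(
        self,
        stimulus: ToneStimulus,
        stage: StageSpec,
        rng: np.random.Generator,
        engaged: bool = True,
    ) -> WheelTrace:
        """Synthesize a wheel trace realizing the sampled choice and latency.

        The trace is flat through the grace period and ramps through the
        decision threshold exactly at the sampled latency, so the trial
        engine's classifier recovers the intended (choice, latency).  A
        disengaged (satiated) agent produces a flat trace (miss).
        """
        p = self.params
        direction: Direction | None = None
        lat: float | None = None
        if engaged:
            if stage.task_kind is TaskKind.DETECTION:
                responded, lat = agent_response_detection(p, stimulus, rng,
                                                          stage.response_window_s)
                if responded:
                    direction = Direction.RIGHT if rng.random() < 0.5 else Direction.LEFT
                else:
                    lat = None
            else:
                direction, lat = agent_choice_discrimination(p, stimulus, stage, rng)
                if direction is not None and self.mapping == "reversed":
                    direction = (Direction.LEFT if direction is Direction.RIGHT
                                 else Direction.RIGHT)
        window = stage.response_window_s
        if direction is None or lat is None:
            return WheelTrace((0.0, window), (0.0, 0.0))
        sign = 1.0 if direction is Direction.RIGHT else -1.0
        peak = sign * (stage.decision_threshold_deg + 5.0)
        grace = stage.grace_period_s
        times = [0.0]
        angles = [0.0]
        if grace > 0.0 and grace < lat:
            times.append(grace)
            angles.append(0.0)
        times.append(lat)
        angles.append(sign * stage.decision_threshold_deg)
        if lat < window:
            times.append(window)
            angles.append(peak)
        return WheelTrace(tuple(times), tuple(angles))

    # --- engagement --------------------------------------------------------

    def satiated(self, water_consumed_ul: float) -> bool:
        return water_consumed_ul >= self.params.daily_water_target_ul

    def next_entry_delay_min(self, rng: np.random.Generator) -> float:
        """Exponential waiting time to the next voluntary tunnel entry."""
        return float(rng.exponential(1.0 / self.params.entry_rate_per_min))

    def aborts_fixation(self, rng: np.random.Generator) -> bool:
        return rng.random() < self.params.abort_prob

    def chains_again(self, rng: np.random.Generator) -> bool:
        """Whether the animal starts another session within the same entry."""
        return rng.random() < self.params.session_chain_prob

    def hold_duration_s(self, rng: np.random.Generator) -> float:
        """Head-hold duration during habituation (exponential, >= 0.5 s)."""
        return 0.5 + float(rng.exponential(self.params.hold_mean_s))


def make_default_cohort(n: int, rng: np.random.Generator) -> list[AgentParams]:
    """A heterogeneous but plausible cohort of ``n`` synthetic mice.

    Parameters jitter log-normally / normally around the defaults; for
    n >= 6 one agent is a 'biased' archetype with a large lapse-side bias,
    mirroring the occasional strongly side-preferring animal.
    """
    if n < 1:
        raise InvalidParameterError("cohort size must be >= 1")
    base = AgentParams()
    cohort: list[AgentParams] = []
    for i in range(n):
        p = replace(
            base,
            disc_pse_octave=float(rng.normal(0.0, 0.03)),
            disc_slope_octave=float(base.disc_slope_octave * rng.lognormal(0.0, 0.2)),
            lapse=float(np.clip(rng.normal(base.lapse, 0.02), 0.005, 0.2)),
            side_bias=float(np.clip(rng.normal(0.0, 0.05), -0.3, 0.3)),
            disc_miss_prob=float(np.clip(rng.normal(base.disc_miss_prob, 0.03), 0.02, 0.3)),
            det_threshold_db_at_best=float(rng.normal(30.0, 2.0)),
            det_threshold_curvature=float(base.det_threshold_curvature * rng.lognormal(0.0, 0.15)),
            lat_base_s=float(np.clip(rng.normal(base.lat_base_s, 0.2), 1.2, 3.2)),
            lat_sd_s=float(np.clip(rng.normal(base.lat_sd_s, 0.1), 0.3, 1.2)),
            entry_rate_per_min=float(np.clip(rng.normal(base.entry_rate_per_min, 0.1), 0.3, 1.2)),
            abort_prob=float(np.clip(rng.normal(base.abort_prob, 0.02), 0.0, 0.2)),
            session_chain_prob=float(np.clip(rng.normal(base.session_chain_prob, 0.04), 0.7, 0.97)),
            daily_water_target_ul=float(np.clip(rng.normal(base.daily_water_target_ul, 200.0),
                                                1800.0, 3200.0)),
        )
        cohort.append(p)
    if n >= 6:
        cohort[n // 2] = replace(cohort[n // 2], side_bias=0.35, lapse=0.12)
    return cohort


# --- parameter-file round trip --------------------------------------------

def save_cohort(cohort: list[AgentParams], fh: IO[str]) -> None:
    json.dump([asdict(p) for p in cohort], fh, indent=2)
    fh.write("\n")


def load_cohort(fh: IO[str]) -> list[AgentParams]:
    return [AgentParams(**d) for d in json.load(fh)]
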
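"""Psychoacoustic analyses of trial and session logs.

Implements the study's standard readouts: per-frequency choice proportions
and a four-parameter sigmoid (logistic) psychometric fit with R²; the
behavioral audiogram obtained by interpolating, at each frequency, the
sound level where the hit rate crosses a criterion (41% by default); the
hit-latency-versus-level linear regression; the maximum hit rate over any
contiguous 50-trial window of a session; and per-day training-history
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .protocol import TaskKind
from .session_manager import SessionRecord
from .trial_engine import Direction, Outcome, TrialRecord


class AnalysisError(ValueError):
    """Base class for analysis failures."""


class InsufficientDataError(AnalysisError):
    pass


class DegenerateFitError(AnalysisError):
    pass


class ConvergenceError(AnalysisError):
    pass


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the analysis DataFrame schema."""
    rows = [
        {
            "day": t.day_index,
            "animal_id": t.animal_id,
            "session_index": t.session_index,
            "trial_index": t.trial_index,
            "stage_id": t.stage_id,
            "task": t.task.value,
            "frequency_hz": t.stimulus.frequency_hz,
            "level_db": t.stimulus.level_db_spl,
            "required_direction": t.required_direction.value,
            "choice": t.choice.value,
            "outcome": t.outcome.value,
            "latency_s": t.latency_s if t.latency_s is not None else np.nan,
            "reward_ul": t.reward_ul,
        }
        for t in trials
    ]
    return pd.DataFrame(rows)


def sessions_to_frame(sessions: Iterable[SessionRecord]) -> pd.DataFrame:
    rows = [
        {
            "day": s.day_index,
            "animal_id": s.animal_id,
            "session_index": s.session_index,
            "stage_id": s.stage_id,
            "min_dur_min": s.min_duration_min,
            "max_dur_min": s.max_duration_min,
            "actual_dur_min": s.actual_duration_min,
            "n_trials": s.n_trials,
            "n_hits": s.n_hits,
            "end_reason": s.end_reason,
        }
        for s in sessions
    ]
    return pd.DataFrame(rows)


# --- psychometric curve ----------------------------------------------------

def proportion_choice_by_frequency(
    trials: pd.DataFrame,
    boundary_hz: float = 20000.0,
    mapping: str = "default",
    include_boundary: bool = False,
) -> pd.DataFrame:
    """Per-frequency proportion of high-side choices in discrimination trials.

    Misses are excluded from the denominator; the boundary tone is excluded
    by default (its 'high-side' label is undefined).  Columns: frequency_hz,
    octave, n_trials, prop_high.
    """
    df = trials[(trials["task"] == TaskKind.DISCRIMINATION.value)
                & (trials["choice"] != Direction.NONE.value)].copy()
    if not include_boundary:
        df = df[df["frequency_hz"] != boundary_hz]
    if df.empty:
        return pd.DataFrame(columns=["frequency_hz", "octave", "n_trials", "prop_high"])
    high_action = Direction.LEFT.value if mapping == "default" else Direction.RIGHT.value
    df["chose_high"] = df["choice"] == high_action
    out = (
        df.groupby("frequency_hz")["chose_high"]
        .agg(n_trials="size", prop_high="mean")
        .reset_index()
        .sort_values("frequency_hz", ignore_index=True)
    )
    out.insert(1, "octave", np.log2(out["frequency_hz"] / boundary_hz))
    out["n_trials"] = out["n_trials"].astype(int)
    return out


@dataclass(frozen=True)
class SigmoidFit:
    base: float
    top: float
    midpoint: float
    slope: float
    r_squared: float

    def predict(self, x):
        return sigmoid_4p(np.asarray(x, dtype=float), self.base, self.top,
                          self.midpoint, self.slope)


def sigmoid_4p(x, base, top, midpoint, slope):
    return base + (top - base) / (1.0 + np.exp(-(x - midpoint) / slope))


def fit_sigmoid_4p(
    x: Sequence[float],
    y: Sequence[float],
    n_per_point: Sequence[float] | None = None,
    maxfev: int = 10000,
) -> SigmoidFit:
    """Weighted least-squares fit of a four-parameter logistic.

    y = base + (top - base) / (1 + exp(-(x - midpoint)/slope)), weights
    proportional to the number of trials behind each point.  R² is computed
    against the weighted mean.  Initialization: base = min(y), top = max(y),
    midpoint = x nearest the half-range crossing, slope = x-range / 5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or np.unique(x).size < 4:
        raise InsufficientDataError("need at least 4 distinct x values")
    if n_per_point is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(n_per_point, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateFitError("y is constant; sigmoid parameters are unidentifiable")

    base0, top0 = float(y.min()), float(y.max())
    half = 0.5 * (base0 + top0)
    mid0 = float(x[np.argmin(np.abs(y - half))])
    slope0 = float(np.ptp(x)) / 5.0
    sigma = 1.0 / np.sqrt(np.maximum(w, 1e-12))
    try:
        popt, _ = curve_fit(
            sigmoid_4p, x, y, p0=(base0, top0, mid0, slope0),
            sigma=sigma, absolute_sigma=False, maxfev=maxfev,
        )
    except RuntimeError as exc:
        raise ConvergenceError(
            f"sigmoid fit did not converge within {maxfev} evaluations "
            f"(n={x.size}, y range [{base0:.3g}, {top0:.3g}]): {exc}"
        ) from exc
    if not np.all(np.isfinite(popt)):
        raise ConvergenceError("sigmoid fit returned non-finite parameters")
    if popt[0] > popt[1]:
        # canonical form: top >= base (the parameterization is symmetric under
        # swapping the asymptotes and negating the slope)
        popt = (popt[1], popt[0], popt[2], -popt[3])

    yhat = sigmoid_4p(x, *popt)
    wmean = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - wmean) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return SigmoidFit(base=float(popt[0]), top=float(popt[1]),
                      midpoint=float(popt[2]), slope=float(popt[3]), r_squared=r2)


def fit_psychometric(
    trials: pd.DataFrame,
    boundary_hz: float = 20000.0,
    mapping: str = "default",
) -> tuple[pd.DataFrame, SigmoidFit]:
    """Choice-proportion table plus its sigmoid fit on the octave axis."""
    table = proportion_choice_by_frequency(trials, boundary_hz, mapping)
    fit = fit_sigmoid_4p(table["octave"], table["prop_high"], table["n_trials"])
    return table, fit


# --- behavioral audiogram --------------------------------------------------

@dataclass(frozen=True)
class Audiogram:
    """Per-frequency detection thresholds at a criterion hit rate."""

    criterion: float
    frequencies_hz: tuple[float, ...]
    thresholds_db: tuple[float, ...]      # NaN where undefined
    defined: tuple[bool, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_hz": self.frequencies_hz,
            "threshold_db": self.thresholds_db,
            "defined": self.defined,
        })

    @property
    def best_frequency_hz(self) -> float:
        """Frequency of minimum (i.e. most sensitive) defined threshold."""
        pairs = [(t, f) for f, t, d in zip(self.frequencies_hz, self.thresholds_db,
                                           self.defined) if d]
        if not pairs:
            raise InsufficientDataError("no frequency has a defined threshold")
        return min(pairs)[1]


def _interpolate_threshold(
    levels: np.ndarray, rates: np.ndarray, criterion: float
) -> float:
    """Lowest level at which the hit rate reaches the criterion.

    Exact equality at a tested level defines the threshold there; otherwise
    the lowest adjacent level pair whose rates rise through the criterion is
    interpolated linearly in dB.  If even the lowest tested level already
    exceeds the criterion, the threshold floors at that level.  Returns NaN
    when the criterion is never reached.
    """
    if rates[0] >= criterion:
        return float(levels[0])
    for i in range(len(levels) - 1):
        r1, r2 = rates[i], rates[i + 1]
        if r1 == criterion:
            return float(levels[i])
        if r1 < criterion <= r2:
            frac = (criterion - r1) / (r2 - r1)
            return float(levels[i] + frac * (levels[i + 1] - levels[i]))
    if rates[-1] == criterion:
        return float(levels[-1])
    return float("nan")


def behavioral_audiogram(trials: pd.DataFrame, criterion: float = 0.41) -> Audiogram:
    """Behavioral audiogram from detection-task trials.

    Per frequency, hit rates are computed at each tested sound level and
    the threshold is the (linearly interpolated) lowest level where the hit
    rate reaches the criterion.  Frequencies that never reach the criterion
    are flagged undefined.
    """
    df = trials[trials["task"] == TaskKind.DETECTION.value]
    if df.empty:
        raise InsufficientDataError("no detection trials")
    if df["level_db"].nunique() < 2:
        raise InsufficientDataError("audiogram needs at least 2 sound levels")
    freqs, thresholds, defined = [], [], []
    for f, grp in df.groupby("frequency_hz"):
        rate = (
            grp.assign(hit=grp["outcome"] == Outcome.HIT.value)
            .groupby("level_db")["hit"].mean()
            .sort_index()
        )
        th = _interpolate_threshold(rate.index.to_numpy(float),
                                    rate.to_numpy(float), criterion)
        freqs.append(float(f))
        thresholds.append(th)
        defined.append(not math.isnan(th))
    return Audiogram(
        criterion=criterion,
        frequencies_hz=tuple(freqs),
        thresholds_db=tuple(thresholds),
        defined=tuple(defined),
    )


# --- latency regression ----------------------------------------------------

@dataclass(frozen=True)
class LatencyRegression:
    slope: float           # s per dB
    intercept: float
    p_value: float         # two-sided t test on the slope
    stderr: float
    n: int


def latency_vs_level(trials: pd.DataFrame) -> LatencyRegression:
    """OLS regression of hit latency on sound level.

    Only hit trials with a recorded latency enter; the p value is the
    two-sided t test on the slope coefficient.
    """
    df = trials[(trials["outcome"] == Outcome.HIT.value)
                & trials["latency_s"].notna()]
    if len(df) < 3:
        raise InsufficientDataError("latency regression needs at least 3 hit trials")
    X = sm.add_constant(df["level_db"].to_numpy(float))
    model = sm.OLS(df["latency_s"].to_numpy(float), X).fit()
    return LatencyRegression(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        stderr=float(model.bse[1]),
        n=len(df),
    )


# --- windowed hit rate and training history --------------------------------

def max_window_hitrate(
    outcomes: Sequence, window: int = 50
) -> float | None:
    """Maximum hit proportion over any contiguous run of exactly ``window``
    trials; None when the sequence is shorter than the window."""
    hits = np.asarray(
        [1 if (o is Outcome.HIT or o == Outcome.HIT.value) else 0 for o in outcomes],
        dtype=float,
    )
    n = hits.size
    if n < window:
        return None
    csum = np.concatenate(([0.0], np.cumsum(hits)))
    window_sums = csum[window:] - csum[:-window]
    return float(window_sums.max() / window)


def training_summary(
    sessions: pd.DataFrame,
    session_outcomes: dict[tuple[str, int], Sequence] | None = None,
    window: int = 50,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Per-day, per-animal training history.

    Columns: day, animal_id, n_sessions, mean_session_duration_min,
    total_fixation_min, total_trials, max_window_hitrate (daily maximum over
    that day's per-session windowed hit rates; NaN when no session reaches
    the window length).  Days with no sessions yield zero rows for every
    animal, not missing rows.  ``session_outcomes`` maps
    (animal_id, session_index) to the session's outcome sequence.
    """
    animals = sorted(sessions["animal_id"].unique()) if len(sessions) else []
    last_day = int(sessions["day"].max()) if len(sessions) else -1
    if n_days is not None:
        last_day = max(last_day, n_days - 1)
    rows = []
    for day in range(last_day + 1):
        day_df = sessions[sessions["day"] == day]
        for aid in animals:
            grp = day_df[day_df["animal_id"] == aid]
            if len(grp):
                rates = []
                if session_outcomes is not None:
                    for si in grp["session_index"]:
                        r = max_window_hitrate(session_outcomes.get((aid, int(si)), []),
                                               window)
                        if r is not None:
                            rates.append(r)
                rows.append({
                    "day": day,
                    "animal_id": aid,
                    "n_sessions": int(len(grp)),
                    "mean_session_duration_min": float(grp["actual_dur_min"].mean()),
                    "total_fixation_min": float(grp["actual_dur_min"].sum()),
                    "total_trials": int(grp["n_trials"].sum()),
                    "max_window_hitrate": max(rates) if rates else float("nan"),
                })
            else:
                rows.append({
                    "day": day, "animal_id": aid, "n_sessions": 0,
                    "mean_session_duration_min": 0.0, "total_fixation_min": 0.0,
                    "total_trials": 0, "max_window_hitrate": float("nan"),
                })
    return pd.DataFrame(rows)


def training_summary_from_records(
    sessions: Sequence[SessionRecord], window: int = 50, n_days: int | None = None
) -> pd.DataFrame:
    frame = sessions_to_frame(sessions)
    outcomes = {(s.animal_id, s.session_index): s.outcomes for s in sessions}
    return training_summary(frame, outcomes, window=window, n_days=n_days)
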
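# Methods

## Scope and design

The package couples a deterministic **protocol engine** (stimulus tables,
trial state machine, session scheduling, stage advancement) to a stochastic
**synthetic mouse** whose generating parameters are known. The engine is
the object of interest; the agent exists so that every engine rule and
every analysis can be validated against ground truth. The agent is
stationary within a stage: it does not learn. Day-scale learning curves in
real animals are therefore outside what the simulation reproduces (see
Limitations).

## Protocol derivation

Stage tables are derived, not transcribed. Discrimination tone sets are
f = B·2^o for a boundary B (20 kHz) and per-stage octave-offset lists;
probabilities are resolved by an exact-rational rule (each *inner* tone,
|o| < 0.5, receives probability 1/20; the four *edge* tones split the
remainder equally), which reproduces the tabulated values 0.5, 0.25,
0.225, 0.2, and 0.1625 exactly (`fractions.Fraction` internally; floats
only at the `StageSpec` boundary). Detection tone sets are geometric grids,
5 tones/octave over ±1.5 octaves around 20 kHz (16 tones, 7.1–56.6 kHz).
Frequencies are stored at full precision; 0.1 kHz rounding is display-only.
One printed value is ambiguous under rounding: 20 kHz·2^−0.0625 =
19.152 kHz displays as 19.2 under round-half-up although tables elsewhere
print 19.1; nothing downstream depends on the displayed value.

## Trial state machine

A trial runs: sample stimulus → agent wheel response → classification →
adjudication → feedback.

* **Classification.** The wheel-angle reference is re-zeroed at the end of
  the grace period (0.1 s in discrimination; 0 in detection), because
  pre-grace motion is discounted and must not contribute displacement. The
  first sample time in (grace, window] whose displacement from that
  reference reaches the decision threshold fixes choice and latency; exact
  threshold equality counts as a crossing (deterministic tie-break).
  Latencies therefore always lie in (grace, window].
* **Feedback.** Hits dispense one drop, volume ~ U(5, 7) µl; a choice made
  before tone offset truncates the tone at the choice latency. Incorrect
  choices receive the stage timeout (4–8 s) and, from D2 on, 0.2 s of
  tactile feedback. Misses receive neither reward nor timeout; detection
  misses are never punished and detection trials cannot be incorrect.
* **Bias correction** (D1/D2) repeats the previous stimulus verbatim until
  the animal scores a hit; misses count as non-hits for this rule, since
  the repeat condition is "until performed correctly". After a hit the
  stage's probability vector applies (uniform in D1/D2 anyway).
* **Trial wall-clock time** = latency (or full window on a miss) + timeout
  + inter-trial interval (default 1 s, configurable). Tactile feedback
  runs concurrently with the timeout.

## Sessions, escalation, days

Session bounds come from the lifetime completed-session count k:
min = min(0.5 + ⌊k/5⌋·0.25, 3) min, max = min(0.5 + ⌊k/5⌋·0.5, 30) min.
The counter never resets (the rule is stated per 5 sessions with no reset
condition). Termination is checked after every completed trial and on 1 s
clock ticks: never before the minimum; then at the maximum, or when the
last five completed trials contain no hit. A trial in progress when the
maximum is reached completes (no trial ever *starts* past the bound).
Running out of cage budget may end a session early (`budget_exhausted`).

Days are event-driven: animals propose tunnel entries as independent
Poisson processes (rate `entry_rate_per_min`) and access is serialized.
An entry costs 0.1 min transit, dispenses one body-beam entry drop
(counted toward daily water; configurable), passes the RFID gate, then
attempts fixation (U(1.5, 2) s anchor extension, per-attempt abort
probability). In HF4 the animal chains sessions within one entry with
probability `session_chain_prob` until satiated or done. HF2/HF3 visits
run the habituation drop schedule instead: one drop per 2 s of continuous
head holding (first drop at 2 s, so 5 drops ⇔ 10 s), counter reset on
withdrawal; HF3 requires a completed fixation and then delivers the full
5-drop, ~10 s mini-fixation. HF1 is scripted (waterspout progression,
nothing to compute) and is represented only as counted days; the default
habituation dwell is 4/2/3 days for HF1/HF2/HF3.

Advancement: D1/D2 and T1 require ≥ 80% hits in some contiguous 50-trial
window within a single session (evaluated over sessions of the current
stage); D3/D4 and T2 require ≥ 50 trials in ≥ 5 of the most recent 10
sessions; D5/T3 are terminal.

## The synthetic mouse

* **Discrimination choice.** With probability `disc_miss_prob` the agent
  does not respond; with probability `lapse` it chooses the high side with
  probability 0.5 + `side_bias`; otherwise P(high) =
  logistic((o − PSE)/slope). The logistic link matches the analysis
  module's sigmoid by construction, which makes parameter recovery an
  identity in expectation (symmetric lapse maps onto the fitted
  asymptotes: base = lapse/2, top = 1 − lapse/2).
* **Detection.** Threshold curve θ(f) = θ_best + c·(log2 f/f_best)², a
  three-parameter U shape with its minimum at f_best = 20 kHz·2^−0.5 =
  14.1 kHz, the region of highest sensitivity in the mouse audiogram.
  P(respond) = guess + (1 − guess − lapse)·logistic((L − θ(f))/s).
* **Latency.** base + slope·L + Gaussian noise, clipped (not resampled) to
  the response window — clipping preserves the monotone mean trend.
  Discrimination default base 2.2 s (mice typically listen into the 2 s
  tone), SD 0.7 s; detection base 0.38 s, SD 0.05 s, kept well inside the
  0.5 s window so the level trend is not flattened against the window
  ceiling; level slope −0.003 s/dB in both.
* **Engagement.** Poisson entries while the day's water intake is below
  `daily_water_target_ul`; once the target is met the animal stops
  entering and stops responding mid-session (the session then ends by the
  five-non-hit rule).

Default engagement values emulate the operating regime the protocol is
designed for — highly water-motivated mice that nearly exhaust their
access window: water target 2500 µl/day (the system is the animal's sole
water source), entry rate 0.6/min, abort probability 0.05, chaining
probability 0.85. Under these defaults a 14-mouse, 30-day cohort averages
≈ 35 min of daily fixation per mouse against the 40 min/mouse budget,
with 100% participation. `make_default_cohort` jitters all parameters
across animals (log-normal/clipped-normal) and includes one strongly
side-biased archetype for n ≥ 6.

## Numerical choices

* Probability resolution in exact rationals; `StageSpec` validates the
  float sum to 1 within 1e-9.
* `fit_sigmoid_4p` uses weighted Levenberg–Marquardt (weights = trials per
  point) with the deterministic initialization base = min y, top = max y,
  midpoint = x nearest the half-range crossing, slope = x-range/5; the fit
  is reported in canonical form top ≥ base (the parameterization is
  symmetric under swapping asymptotes and negating the slope). R² is
  computed against the weighted mean because points carry unequal trial
  counts. Constant y raises a degenerate-fit error; non-convergence raises
  a convergence error with diagnostics.
* Audiogram thresholds interpolate linearly in dB within the lowest
  adjacent level pair whose hit rates rise through the criterion; exact
  equality at a tested level defines the threshold there; if even the
  lowest tested level exceeds the criterion the threshold floors at that
  level. These conventions make the threshold monotone: raising every hit
  rate can never raise a defined threshold.
* All randomness flows from one integer seed: animal i draws from
  `PCG64(SeedSequence([seed, i]))`, the cohort generator from spawn key
  `[seed, 2**20]`. Event ordering is deterministic (ties broken by animal
  id), so identical seed + config reproduce byte-identical CSV/JSON logs
  (floats serialized via shortest round-trip `repr`).

## Problem sizes

The shipped checks use 2000 discrimination trials for psychometric
recovery, 5000 detection hits for the latency regression, 112 000
detection trials for the audiogram (≈ 1000 per frequency × level cell,
enough to resolve the 0.6 dB threshold spacing between tones adjacent to
the minimum), 200 000 draws for the stimulus-distribution goodness-of-fit,
and a 14-animal × 30-day cohort for the end-to-end run.

## Limitations

* No learning: stage progression reflects competence plus the advancement
  bookkeeping, so synthetic mice traverse D1→D5 in days, not weeks, and
  the slow rise of windowed hit rate seen in real training histories is
  not reproduced.
* Trial pacing is response-limited; real mice pause within sessions, so
  simulated trials/day (≈ 500) exceed typical animal counts (≈ 300) even
  at matched fixation time.
* Wheel traces are synthesized ramps realizing the sampled
  (choice, latency); continuous wheel physics, licking dynamics, servo
  kinematics, beam-break debouncing and audio calibration are out of
  scope, as is multi-animal physical queuing beyond serialized access.
* Real-animal headline statistics (e.g. a specific fit R² or latency
  slope in other units) depend on live data and are mirrored only
  qualitatively by the synthetic cohort.
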
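# headfix

Simulation and analysis toolkit for **automated voluntary head-fixation
training** of mice on two-alternative forced-choice (2AFC) auditory tasks.

Homecage systems that let a mouse walk into a tunnel, get head-fixed by its
own choice, work for water, and leave again replace weeks of stressful
manual training with self-paced sessions. This package implements the full
training engine for such a system — the habituation ladder (HF1–HF4), a
frequency-discrimination task around a 20 kHz category boundary (stages
D1–D5), a tone-detection task across sound levels (T1–T3), the
session-duration escalation rule, the daily cage access budget, and stage
advancement — together with synthetic mouse agents with known ground-truth
psychometrics, so that every piece of engine and analysis code is testable
against its generating process.

It is aimed at behavioral neuroscientists and engineers who want to
prototype, audit, or regression-test an automated training protocol before
(or instead of) pointing it at animals.

## The protocol in brief

* **Discrimination (D1–D5).** Tones at octave offsets
  o ∈ {−1, −0.5, −0.25, −0.125, −0.0625, 0, …, +1} re 20 kHz
  (f = 20 kHz · 2^o), 2 s long, 10 Hz amplitude-modulated, 70 dB SPL. Low
  tones (< 20 kHz) require a rightward wheel turn, high tones leftward;
  20 kHz rewards either direction. After a 0.1 s grace period the first
  wheel excursion beyond the decision threshold (5–10°) within 4 s defines
  the choice; correct → one 5–7 µl drop and tone truncation, incorrect →
  4–8 s silent timeout plus 0.2 s vibration, no crossing → miss. Inner
  tones are presented with probability 0.05 each; the four edge tones
  (10, 14.1, 28.3, 40 kHz) split the remainder — e.g. 0.1625 each in D5.
  D1/D2 repeat the same tone after every non-hit (bias correction).
* **Detection (T1–T3).** 16 tones, 5 per octave from 7.1 to 56.6 kHz,
  0.2 s long, levels 70 down to 10 dB SPL; any turn within 0.5 s is a hit,
  misses are not punished.
* **Sessions.** Minimum/maximum session duration start at 0.5/0.5 min and
  grow by 0.25/0.5 min per 5 completed sessions, capped at 3/30 min. Once
  the minimum is reached a session ends at the maximum or after 5
  consecutive trials without a hit. A cage's daily tunnel access is
  40 min × (number of mice).
* **Analyses.** Psychometric curves p(choose high | o) fitted with
  y = base + (top − base) / (1 + exp(−(o − m)/s)) and weighted R²; the
  behavioral audiogram as the per-frequency sound level interpolated at a
  41% hit-rate criterion; OLS regression of hit latency on sound level;
  maximum hit rate over any contiguous 50-trial window; per-day training
  histories.

## Worked example

```bash
headfix simulate --seed 1 --days 5 --n-mice 4 --out demo
# wrote 10418 trials over 5 days to demo

headfix analyze psychometric --trials demo/trials.csv --out demo/psy.csv
# sigmoid fit: base=0.0418 top=0.9645 midpoint=-0.0230 oct slope=0.1789 oct R^2=0.9997
```

Four synthetic mice train for five simulated days; the fitted psychometric
midpoint (−0.023 octaves, i.e. the point of subjective equality sits just
below 20 kHz) and slope (0.18 octaves) recover the cohort's generating
parameters, and the sigmoid describes the pooled choice curve with
R² ≈ 1.00. For the detection task:

```bash
headfix simulate --seed 2 --days 6 --n-mice 4 --task detection --out demo_det
headfix analyze audiogram --trials demo_det/trials.csv --out demo_det/aud.csv
# best frequency: 14.1 kHz (criterion 0.41)

headfix analyze latency --trials demo_det/trials.csv
# slope=-0.003003 s/dB intercept=0.3801 s p=0 n=10758
```

The audiogram's most sensitive frequency (14.1 kHz) and the negative
latency-versus-level slope (−0.003 s/dB: softer tones, slower responses)
match the agents' generating model. `headfix validate` re-derives the
stage tables from the protocol rules and confirms the printed constants
(D5 edge probability 0.1625, 16 detection tones up to 56.6 kHz), and
`headfix fixtures` emits the default protocol JSON, a cohort parameter
file, and a small golden trial log.

## Layout

| module | contents |
| --- | --- |
| `headfix.protocol` | stage tables (derived, exact-rational probabilities), tone-set constructors, JSON round-trip |
| `headfix.trial_engine` | stimulus sampling with bias correction, wheel-trace classification, adjudication, feedback, CSV logs |
| `headfix.session_manager` | duration escalation, termination rule, advancement, habituation entries, day scheduler, cohort driver |
| `headfix.mouse_agent` | generative mouse: logistic psychometrics with lapse, U-shaped audiogram, latency model, engagement |
| `headfix.analysis` | psychometric fits, behavioral audiogram, latency regression, windowed hit rates, training histories |
| `headfix.io_cli` | run configuration (validated JSON), output writers, `headfix` command-line interface |

See `docs/methods.md` for the behavioral model, parameter defaults, and
numerical choices.
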
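# finchloop

An in-silico re-implementation of a closed-loop songbird conditioning
experiment: synthetic zebra-finch-like agents are coupled to the real-time
machinery that delivers brief aversive/appetitive feedback contingent on
either the **pitch of a target song syllable** or **occupancy of a target
perch**, and the behavioral read-outs and statistics are recovered from the
resulting event logs.

The scientific question the original experiment poses is whether different
behaviors are trained by one global reinforcement signal or by
behavior-specific signals. The simulated architecture is explicitly
multi-agent: a 75 ms band-limited noise burst is *aversive to the vocal
system* (birds shift syllable pitch to escape it) yet *appetitive to the
navigation system* (birds seek the perch that triggers it), while a 75 ms
strobe light is *aversive to navigation only* and cannot move pitch at all.

## What the pipeline contains

- **`synthetic_bird`** — generates every input: harmonic-stack song motifs
  at 40 kHz with a designated target syllable whose fundamental varies
  rendition to rendition; a Gaussian vocal-rendition learner with separate
  auditory and visual couplings (the visual coupling is zero by default);
  a softmax place-preference agent over two perches plus an off-perch
  state, with valence accumulators updated per delivered stimulus; and a
  lights-on/lights-off day schedule outside which nothing happens.
- **`syllable_detector`** — amplitude-envelope segmentation (2 ms moving
  RMS, hysteresis), target selection by Butterworth band-pass spectral
  feature or by inter-onset interval, and the programmable 10–200 ms delay
  from detection to the pitch window.
- **`pitch_contingency`** — the 6 ms FFT pitch measurement (zero-padded,
  Hann-windowed, parabolic peak interpolation, divided by the harmonic
  number), baseline-median threshold initialization, the every-400-
  renditions median ratchet, and the hit/escape decision (hit = measured
  pitch strictly below the threshold).
- **`feedback_controller`** — exact stimulus timing and rendering: the
  75 ms noise burst band-limited to 1.5–8 kHz at 88 dB (−20 dBFS), the
  75 ms strobe pattern (5 ms on / 65 ms dark / 5 ms on), perch trains at
  landing + 1 ms then 2 ± 0.25 Hz, and pitch-triggered delivery 0–2 ms
  after the measurement window.
- **`behavior_metrics`** — landing rate, occupancy (lights-off excluded
  from every denominator), singing/non-singing occupancy splits (singing
  = 1 s before onset to 1 s after offset), daily pitch change, one- and
  two-sample t tests, and the two-way condition × singing-state ANOVA.
- **`experiment_runner`** — closed-loop sessions for all four
  contingencies with reversal support, deterministic per-(bird, day)
  seeding, artifact directories with checksum manifests, and a
  `reproduce_experiment_suite` that runs the whole experimental program.

## Worked example

Run a pitch-contingent noise session with the vocal agent calibrated to a
daily shift of 8.8 Hz/day, and re-estimate that shift from the simulated
rendition logs:

```python
import finchloop as fl
from finchloop.experiment_runner import SessionConfig, run_session
from finchloop.feedback_controller import ContingencyConfig

vocal = fl.calibrated_vocal_agent(8.8)  # target effect: 8.8 Hz/day
cfg = SessionConfig(
    birds=2,
    contingency=ContingencyConfig(mode="pitch_noise"),
    vocal=vocal,
    master_seed=7,
)
res = run_session(cfg)
daily = res.renditions.query("phase == 'contingency'").groupby("day")["pitch_hz"].mean()
print(daily.round(1))
print("group daily pitch change:", round(res.stats["group_delta_hz_per_day"], 2), "Hz/day")
```

prints

```
day
5    605.5
6    615.1
7    622.8
8    632.9
Name: pitch_hz, dtype: float64
group daily pitch change: 9.13 Hz/day
```

Days 0–4 are the undistorted baseline; the feedback threshold is
initialized to the day-4 (fifth baseline day) median. From day 5 onward,
every rendition whose measured pitch falls below the ratcheting threshold
triggers a noise burst, and the daily mean climbs by roughly the
calibrated 8.8 Hz/day (9.13 here, within the two-bird sampling error).
Each rendition's pitch is *measured*, not read off the generator: the
motif is synthesized, segmented on its amplitude envelope, the pre-target
syllable is matched in its unique feature band, and a 6 ms FFT window is
placed into the target's harmonic stack by the trigger delay.

A command-line interface mirrors the stages
(`finchloop simulate|detect|contingency|feedback|analyze|reproduce`), e.g.

```bash
finchloop reproduce --out results/suite --seed 0
```

runs all four contingencies plus the singing-split analyses.

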
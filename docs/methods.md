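# Methods

This note documents the models, numerical choices, and calibrations behind
the pipeline, and what the synthetic experiments do and do not establish.

## The simulated experiment

One session couples a synthetic bird to the closed-loop controller under
exactly one of four contingencies: perch-contingent strobe, perch-
contingent noise, pitch-contingent noise, or pitch-contingent strobe. The
loop is event-driven at bout/rendition granularity rather than streamed
sample by sample: for the vocal path, audio is synthesized per rendition
and pushed through the detection and measurement DSP; for the place path,
occupancy bouts and their stimulus trains are generated directly. This
keeps a multi-bird, multi-day experiment to seconds–minutes of CPU while
every decision (segmentation, feature match, pitch measurement, threshold
comparison, stimulus timing) is made by the same code path an online
system would run on recorded buffers.

## Song model

Syllables are harmonic stacks: equal-amplitude partials at integer
multiples of a fundamental, shaped by a linear attack/sustain/decay
envelope, band-limited below 8 kHz and synthesized at 40 kHz. The default
motif is three syllables (fundamentals 480 Hz × 8 harmonics, 2.5 kHz × 2,
600 Hz × 8) with 60 ms gaps; the third syllable is the conditioning
target and the second carries a spectral feature near 2.5 kHz that is
unique within the motif, which is what the spectral-feature trigger keys
on. Rendition-to-rendition pitch variation applies only to the target
syllable.

This is deliberately not a model of real zebra finch acoustics: no
frequency modulation, no amplitude noise, no syntax variability, no
background noise. Consequences for interpretation: detector and pitch-
measurement accuracies measured here (≥95% targeting, sub-Hz pitch error)
are upper bounds that real recordings would not reach; the pipeline's
*contracts* (what is computed, when stimuli fire, how thresholds move)
are what the tests establish.

## Vocal learning agent

Rendition pitches are drawn i.i.d. from N(μ, σ) with σ = 25 Hz by
default, a typical rendition-to-rendition spread for a harmonic syllable.
Learning is a phenomenological escape rule: each *hit* (penalized
rendition) moves μ away from the penalized side by a fixed step
`rate × σ` Hz, where `rate` is `auditory_learning_rate` for noise
feedback and `visual_learning_rate` for strobe. The visual coupling is 0
by default — this is the architectural claim under test, wired in: strobe
hits are identity operations on the vocal state, so any flat pitch
trajectory under pitch-contingent strobe is a consequence of the wiring,
and the corresponding test verifies the pipeline *estimates* it as flat.

**Calibration.** The per-hit step is set so the closed loop's expected
daily shift equals a target (8.8 Hz/day for the noise condition).
Because hits depend on the threshold, which ratchets to trailing medians,
which depend on past learning, the expectation is computed by iterating
the deterministic mean-trajectory recursion: per rendition the hit
probability is Φ((thr − μ)/σ) and μ advances by `step × p_hit`; per
400-rendition block the threshold ratchets to the block's mean trajectory
value (a proxy for the pooled median, exact in the symmetric limit). The
step solving `expected_daily_change(step) = target` is found by Brent
root finding. The same estimator the metrics stage uses (mean of
consecutive-day mean differences) is applied inside the recursion, so
calibration and recovery measure the same quantity. Stochastic runs at
5 birds × 4 days × 400 renditions recover the target within their
Monte-Carlo CI (typically ±0.5 Hz/day).

## Place preference agent

The agent repeatedly chooses among perch 1, perch 2, and an explicit
off-perch state by softmax over values (v₁, v₂, v_off)/T, then dwells an
exponential time (mean 15 s on a perch, 30 s off; off-perch value 1.0,
T = 1, so a naive bird spends most of its time off the test perches).
Every delivered stimulus nudges the occupied perch's value toward the
stimulus valence: v ← v + α(valence − v) with α = 0.05, applied in closed
form per bout. At saturation v equals the valence, so the asymptotic
landing logit between perches is valence/T — which makes calibration to a
printed preference closed-form: valence = T·logit(p).

Defaults wire noise appetitive (valence = logit(0.86) ≈ +1.82) and strobe
aversive (−logit(0.813) ≈ −1.47), the group preferences of the two perch
experiments. Occupancy can differ from landing rate only through dwell
asymmetry; per-perch dwell scale factors are therefore part of
calibration (for the strobe condition, matching 81.3% landings but 73.7%
occupancy on the safe perch requires the safe-perch dwell to be 0.64× the
strobed-perch dwell — the printed numbers imply birds made fewer but
longer visits to the strobed perch).

Accumulators also shrink toward zero by 50% at each day boundary
("overnight forgetting"). The maintained contingency re-saturates within
minutes the next morning, so steady-state metrics are unaffected; a
*reversed* contingency lets the formerly stimulated perch relax to
neutral over a few days, which is what re-expresses the mirrored
preference after reversal instead of leaving two equally-valued perches.

Nothing here models real navigation: no spatial continuity, no
exploration/exploitation dynamics, no circadian structure within the day.
The agent exists to give the analysis stage event streams whose
ground-truth preference is known and controllable.

## Detection and pitch measurement

- Amplitude envelope: moving RMS over 2 ms, DC removed. Segments are
  maximal runs above 0.8× the onset threshold that reach the onset
  threshold at least once (hysteresis); gaps < 15 ms merge, segments
  < 15 ms drop. Thresholding is idempotent and DC-insensitive.
- Spectral feature match: order-4 Butterworth band-pass, zero-phase
  (`sosfiltfilt`), statistic = filtered power / total power, threshold
  0.3. The filter family is fixed by the experimental description; order
  and statistic are package choices.
- Detection timestamp: offset of the matched pre-target segment in
  spectral mode, onset of the target segment in inter-onset-interval
  mode; the 10–200 ms trigger delay then sets the start of the 6 ms
  pitch window (default 100 ms, placing the window ~40 ms into the
  default target syllable's sustain).
- Pitch: 6 ms (240-sample) window, Hann, zero-padded ×64, magnitude peak
  within the configured harmonic band refined by parabolic interpolation
  on log magnitude, divided by the harmonic number. Native resolution at
  6 ms is ~167 Hz; padding plus interpolation brings clean-stack error
  below 1 Hz (tested bound: ≤5 Hz across fundamentals 400–800 Hz). The
  default band (1050–1450 Hz, 2nd harmonic) brackets the entire
  rendition distribution of the default target (μ = 600, σ = 25) even
  after several days of upward learning, without admitting a neighboring
  harmonic.
- Ties at the threshold escape; the 400-rendition update window is
  tumbling (non-overlapping), and an even-length median is the mean of
  the central pair.

## Stimulus timing

The repeat schedule reads "2 ± 0.25 Hz" as deliberate jitter: each
inter-stimulus interval is 1/f with f ~ U(1.75, 2.25) Hz, giving
long-run rates inside the band and a 2.0 Hz mean. The alternative reading
(fixed 2 Hz, ±0.25 as hardware tolerance) would be a special case
(`repeat_jitter_hz=0`). The first stimulus fires 1 ms after landing; no
onset occurs after the bird leaves, but a stimulus that begins before
departure is not truncated. Pitch-triggered stimuli fire U(0, 2) ms after
the 6 ms window ends. Sound level is digital: the 88 dB physical
calibration maps to −20 dBFS RMS (dBFS = dB − 108), since SPL is not
realizable in software. The noise burst is band-limited by zeroing
out-of-band DFT bins — an exact brickwall band-pass, so the ≥99% in-band
contract holds identically rather than approximately.

## Metrics and statistics

Landing rate and occupancy are ratios over the two test perches only,
with every bout clipped to lights-on; zero denominators propagate as
missing (NaN), never zero. The singing state runs from 1 s before a song
onset to 1 s after the offset; padded epochs are merged so gaps under 2 s
never split a singing interval, and the track tiles the lights-on day
exactly. Daily pitch change is the mean of consecutive-day differences in
daily mean pitch, with days under 20 renditions excluded (the minimum is
a package choice). The t tests are classical (two-sided; two-sample with
pooled variance); zero-variance samples are flagged degenerate. The
two-way ANOVA (condition × singing state, with interaction) uses Type II
sums of squares over bird-day rows, matching the degrees-of-freedom
structure of the original analysis; on balanced tables Type II equals the
textbook decomposition, which the tests verify against hand-computed sums
of squares.

## Seeding and problem sizes

All randomness descends from one master seed through
`SeedSequence([master_seed, bird, day, stream])`, so any (bird, day) is
independently reproducible and whole sessions are bit-identical across
reruns (verified by checksum manifests). The standard problem sizes used
by the tests and the acceptance script — chosen as the package's
desk-scale defaults — are: 5 birds × (5 baseline + 4 contingency) days ×
400 renditions/day for pitch-contingent noise; 20 single-seed birds at
100 renditions/day for the strobe null; 5 birds × 3 days and 6 birds ×
4 days of 14 h lights-on for the two perch experiments; 1000 s bouts for
repeat-rate checks.

## Known limitations

- Baseline days 1–4 log generator ground truth directly; only the final
  baseline day (which sets the threshold) and contingency days run the
  full DSP path.
- The bout/gap structure of song (2–4 motifs per bout, ≥2 s inter-bout
  silences) and all singing-rate parameters are arbitrary defaults; no
  published statistics constrain them, and none of the recovered effects
  depend on them beyond the 1 s singing-state rule.
- Learning rules are phenomenological stand-ins chosen to be minimal and
  calibrate cleanly; they make no mechanistic claims.
- The detector emulates causal decisions on recorded buffers; there are
  no real-time latency guarantees.
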
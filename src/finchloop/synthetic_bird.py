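"""Synthetic bird: song synthesis, vocal learning, and place preference.

This module generates every input the rest of the pipeline consumes.

*Song* is modelled as motifs of harmonic-stack syllables. One syllable in
the motif is the conditioning target; its fundamental varies rendition to
rendition around the vocal agent's current mean.

*Two agents, two reinforcers.* The architecture under study routes each
feedback stimulus to a behavior-specific learning system:

- The **vocal agent** holds a Gaussian rendition distribution
  ``N(pitch_mean_hz, pitch_sd_hz)``. Auditory feedback (noise) on a hit
  shifts the mean away from the penalized pitch region; visual feedback
  (strobe) is scaled by a separate coupling that is zero by default, so
  strobe cannot move the pitch distribution.
- The **place agent** chooses between two test perches and an off-perch
  state by softmax over perch-value accumulators. Each delivered stimulus
  nudges the occupied perch's value toward the stimulus valence
  (``v <- v + alpha * (valence - v)``). Noise carries positive valence
  (birds seek the noisy perch) and strobe negative valence (birds avoid
  the strobed perch); both signs are configurable.

Generators are pure functions of (configuration, seed); per-day and
per-bird streams are split from one master seed via
:func:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import ndtr

from .audio import DEFAULT_SAMPLE_RATE, AudioBuffer
from .events import PerchEvent, StimulusEvent
from .feedback_controller import ContingencyConfig, _stimulus_onsets


def make_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Child generator for stream ``key`` (e.g. bird, day) of a master seed.

    Uses ``SeedSequence([master_seed, *key])`` so every (seed, key) pair
    maps to an independent, reproducible stream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


class AliasingError(ValueError):
    """Requested harmonics would exceed the Nyquist frequency."""


# ---------------------------------------------------------------------------
# Song synthesis
# ---------------------------------------------------------------------------


class SyllableSpec(BaseModel):
    """A harmonic-stack syllable template.

    ``amplitude_envelope`` is (attack, sustain, decay) fractions of the
    duration, summing to 1: linear rise, flat sustain, linear fall.
    """

    model_config = {"frozen": True}

    fundamental_hz: float = Field(gt=0)
    n_harmonics: int = Field(ge=1)
    duration_ms: float = Field(gt=6.0)  # must contain the 6 ms pitch window
    amplitude_envelope: tuple[float, float, float] = (0.15, 0.65, 0.20)
    band_limit_hz: float = 8000.0

    @model_validator(mode="after")
    def _check(self) -> "SyllableSpec":
        if self.fundamental_hz * self.n_harmonics > self.band_limit_hz:
            raise ValueError(
                f"highest harmonic {self.fundamental_hz * self.n_harmonics:.0f} Hz "
                f"exceeds band limit {self.band_limit_hz:.0f} Hz"
            )
        if abs(sum(self.amplitude_envelope) - 1.0) > 1e-9 or min(self.amplitude_envelope) < 0:
            raise ValueError("amplitude_envelope fractions must be >=0 and sum to 1")
        return self


class MotifSpec(BaseModel):
    """An ordered run of syllables with silent gaps, one of them the target."""

    model_config = {"frozen": True}

    syllables: tuple[SyllableSpec, ...]
    gaps_ms: tuple[float, ...]
    target_index: int

    @model_validator(mode="after")
    def _check(self) -> "MotifSpec":
        if len(self.gaps_ms) != len(self.syllables) - 1:
            raise ValueError("need exactly one gap between each pair of syllables")
        if any(g <= 0 for g in self.gaps_ms):
            raise ValueError("all gaps must be positive")
        if not (0 <= self.target_index < len(self.syllables)):
            raise ValueError("target_index does not address a syllable")
        return self


def default_motif() -> MotifSpec:
    """Three-syllable motif whose pre-target syllable carries a unique
    spectral feature near 2.5 kHz, usable as the detector's template."""
    return MotifSpec(
        syllables=(
            SyllableSpec(fundamental_hz=480.0, n_harmonics=8, duration_ms=100.0),
            SyllableSpec(fundamental_hz=2500.0, n_harmonics=2, duration_ms=80.0),
            SyllableSpec(fundamental_hz=600.0, n_harmonics=8, duration_ms=140.0),
        ),
        gaps_ms=(60.0, 60.0),
        target_index=2,
    )


@lru_cache(maxsize=256)
def _render_stack(
    fundamental_hz: float,
    n_harmonics: int,
    duration_ms: float,
    envelope: tuple[float, float, float],
    sample_rate: int,
    peak_amplitude: float,
) -> np.ndarray:
    n = int(round(duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        wave += np.sin(2.0 * np.pi * k * fundamental_hz * t)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave /= peak
    attack, _sustain, decay = envelope
    n_a = int(round(attack * n))
    n_d = int(round(decay * n))
    env = np.ones(n)
    if n_a > 0:
        env[:n_a] = np.linspace(0.0, 1.0, n_a, endpoint=False)
    if n_d > 0:
        env[n - n_d :] = np.linspace(1.0, 0.0, n_d)
    out = wave * env * peak_amplitude
    out.setflags(write=False)  # cached: shared between callers
    return out


def synthesize_syllable(
    spec: SyllableSpec,
    rendition_pitch_hz: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    peak_amplitude: float = 0.8,
) -> AudioBuffer:
    """Render one syllable at a given rendition fundamental.

    Equal-amplitude harmonics at integer multiples of the rendition pitch,
    shaped by the attack/sustain/decay envelope.
    """
    nyquist = sample_rate / 2.0
    if rendition_pitch_hz * spec.n_harmonics > nyquist:
        raise AliasingError(
            f"harmonic {spec.n_harmonics} x {rendition_pitch_hz:.0f} Hz exceeds "
            f"Nyquist {nyquist:.0f} Hz"
        )
    samples = _render_stack(
        float(rendition_pitch_hz),
        spec.n_harmonics,
        spec.duration_ms,
        spec.amplitude_envelope,
        sample_rate,
        peak_amplitude,
    )
    return AudioBuffer(samples, sample_rate)


def synthesize_motif(
    motif: MotifSpec,
    target_pitch_hz: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> tuple[AudioBuffer, list[tuple[float, float]]]:
    """Render one motif instance; returns (audio, [(onset_s, offset_s)] per syllable).

    Non-target syllables are rendered at their template fundamental; the
    target at ``target_pitch_hz``.
    """
    chunks: list[np.ndarray] = []
    spans: list[tuple[float, float]] = []
    t = 0.0
    for i, syl in enumerate(motif.syllables):
        pitch = target_pitch_hz if i == motif.target_index else syl.fundamental_hz
        buf = synthesize_syllable(syl, pitch, sample_rate)
        chunks.append(buf.samples)
        spans.append((t, t + buf.duration_s))
        t += buf.duration_s
        if i < len(motif.gaps_ms):
            gap_n = int(round(motif.gaps_ms[i] / 1000.0 * sample_rate))
            chunks.append(np.zeros(gap_n))
            t += gap_n / sample_rate
    return AudioBuffer(np.concatenate(chunks), sample_rate), spans


# ---------------------------------------------------------------------------
# Vocal agent
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VocalAgentState:
    """Gaussian rendition model with escape-driven mean shift.

    Rendition pitches are drawn ``N(pitch_mean_hz, pitch_sd_hz)``. A hit
    moves the mean away from the penalized side by
    ``learning_rate * pitch_sd_hz`` Hz, where the rate is
    ``auditory_learning_rate`` for noise feedback and
    ``visual_learning_rate`` for strobe. The visual coupling defaults to
    zero: strobe feedback leaves the pitch distribution invariant.
    ``daily_drift_hz`` is an optional deterministic baseline drift applied
    at day boundaries (default none).
    """

    pitch_mean_hz: float = 600.0
    pitch_sd_hz: float = 25.0
    auditory_learning_rate: float = 0.0024
    visual_learning_rate: float = 0.0
    daily_drift_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.pitch_sd_hz <= 0:
            raise ValueError("pitch_sd_hz must be positive")
        if self.auditory_learning_rate < 0 or self.visual_learning_rate < 0:
            raise ValueError("learning rates must be >= 0")


def vocal_update(
    vocal: VocalAgentState,
    rendition_pitch_hz: float,
    outcome: Literal["hit", "escape"],
    stimulus: Literal["noise", "strobe"],
    direction: Literal["below", "above"] = "below",
) -> VocalAgentState:
    """One rendition's worth of vocal learning.

    Escapes leave the state unchanged. A hit shifts the mean away from the
    penalized side of the threshold (up for ``direction="below"``), scaled
    by the stimulus-appropriate coupling; with the default zero visual
    coupling, strobe hits are identity.
    """
    if outcome != "hit":
        return vocal
    rate = vocal.auditory_learning_rate if stimulus == "noise" else vocal.visual_learning_rate
    if rate == 0.0:
        return vocal
    step = rate * vocal.pitch_sd_hz
    sign = 1.0 if direction == "below" else -1.0
    return replace(vocal, pitch_mean_hz=vocal.pitch_mean_hz + sign * step)


def expected_daily_pitch_change(
    per_hit_step_hz: float,
    renditions_per_day: int = 400,
    pitch_sd_hz: float = 25.0,
    contingency_days: int = 4,
    block_size: int = 400,
) -> float:
    """Deterministic mean-trajectory prediction of the closed loop's daily shift.

    Iterates the expected mean-pitch recursion: per rendition the hit
    probability is ``Phi((thr - mu)/sd)`` and the mean advances by
    ``step * p_hit``; after each tumbling block the threshold ratchets to
    the block median (approximated by the mean of the block's means).
    Returns the average of consecutive-day mean differences — the same
    estimator the metrics stage applies to simulated logs.
    """
    mu, thr = 0.0, 0.0  # relative to baseline; threshold starts at baseline median
    day_means = []
    block: list[float] = []
    for _ in range(contingency_days):
        mus = np.empty(renditions_per_day)
        for r in range(renditions_per_day):
            mus[r] = mu
            block.append(mu)
            p_hit = float(ndtr((thr - mu) / pitch_sd_hz))
            mu += per_hit_step_hz * p_hit
            if len(block) == block_size:
                thr = max(thr, float(np.mean(block)))
                block.clear()
        day_means.append(float(mus.mean()))
    return float(np.mean(np.diff(day_means))) if len(day_means) > 1 else float("nan")


def calibrated_vocal_agent(
    target_hz_per_day: float,
    renditions_per_day: int = 400,
    pitch_mean_hz: float = 600.0,
    pitch_sd_hz: float = 25.0,
    contingency_days: int = 4,
    block_size: int = 400,
) -> VocalAgentState:
    """Vocal agent whose expected closed-loop daily shift equals the target.

    Solves the deterministic mean-trajectory recursion (see
    :func:`expected_daily_pitch_change`) for the per-hit step by root
    finding, then expresses it as a dimensionless rate.
    """
    if target_hz_per_day <= 0:
        raise ValueError("target shift must be positive")

    def gap(step: float) -> float:
        return (
            expected_daily_pitch_change(
                step, renditions_per_day, pitch_sd_hz, contingency_days, block_size
            )
            - target_hz_per_day
        )

    step = brentq(gap, 1e-6, pitch_sd_hz, xtol=1e-6)
    return VocalAgentState(
        pitch_mean_hz=pitch_mean_hz,
        pitch_sd_hz=pitch_sd_hz,
        auditory_learning_rate=step / pitch_sd_hz,
        visual_learning_rate=0.0,
    )


# ---------------------------------------------------------------------------
# Song day generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SongDay:
    """One day of synthesized song with its ground-truth logs.

    ``renditions`` has one row per target-syllable rendition
    (``rendition, bout, prev_onset_s, target_onset_s, target_offset_s,
    pitch_hz``); ``syllables`` has one row per syllable instance
    (``rendition, syllable, onset_s, offset_s, is_target``).
    """

    audio: AudioBuffer
    renditions: pd.DataFrame
    syllables: pd.DataFrame


def generate_song_day(
    motif: MotifSpec,
    vocal: VocalAgentState,
    n_renditions: int,
    seed: int | np.random.Generator,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    motifs_per_bout: tuple[int, int] = (2, 4),
    intra_bout_gap_s: tuple[float, float] = (0.3, 0.6),
    inter_bout_silence_s: float = 2.0,
) -> SongDay:
    """Synthesize a day of song: bouts of motifs separated by >= 2 s silence.

    Rendition pitches for the target syllable are drawn from the vocal
    agent's current distribution. The returned ground-truth logs are what
    detector validation is scored against. Bit-identical for a fixed seed.
    """
    if n_renditions < 1:
        raise ValueError("need at least one rendition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pitches = rng.normal(vocal.pitch_mean_hz, vocal.pitch_sd_hz, size=n_renditions)

    chunks: list[np.ndarray] = [np.zeros(int(0.5 * sample_rate))]
    t = 0.5
    rendition_rows, syllable_rows = [], []
    r = 0
    bout = 0
    while r < n_renditions:
        bout_size = min(int(rng.integers(motifs_per_bout[0], motifs_per_bout[1] + 1)),
                        n_renditions - r)
        for j in range(bout_size):
            buf, spans = synthesize_motif(motif, float(pitches[r]), sample_rate)
            for s_idx, (on, off) in enumerate(spans):
                syllable_rows.append(
                    {
                        "rendition": r,
                        "syllable": s_idx,
                        "onset_s": t + on,
                        "offset_s": t + off,
                        "is_target": s_idx == motif.target_index,
                    }
                )
            tgt_on, tgt_off = spans[motif.target_index]
            prev_on = spans[motif.target_index - 1][0] if motif.target_index > 0 else np.nan
            rendition_rows.append(
                {
                    "rendition": r,
                    "bout": bout,
                    "prev_onset_s": t + prev_on if not np.isnan(prev_on) else np.nan,
                    "target_onset_s": t + tgt_on,
                    "target_offset_s": t + tgt_off,
                    "pitch_hz": float(pitches[r]),
                }
            )
            chunks.append(buf.samples)
            t += buf.duration_s
            r += 1
            if j < bout_size - 1:
                gap = rng.uniform(*intra_bout_gap_s)
                chunks.append(np.zeros(int(round(gap * sample_rate))))
                t += int(round(gap * sample_rate)) / sample_rate
        silence = inter_bout_silence_s + rng.exponential(0.5)
        chunks.append(np.zeros(int(round(silence * sample_rate))))
        t += int(round(silence * sample_rate)) / sample_rate
        bout += 1
    audio = AudioBuffer(np.concatenate(chunks), sample_rate)
    return SongDay(audio, pd.DataFrame(rendition_rows), pd.DataFrame(syllable_rows))


# ---------------------------------------------------------------------------
# Schedule and place agent
# ---------------------------------------------------------------------------


class DaySchedule(BaseModel):
    """Lights-on window per day. No song or perch activity during lights-off."""

    model_config = {"frozen": True}

    lights_on_s: float = 25_200.0  # 07:00
    lights_off_s: float = 75_600.0  # 21:00
    n_days: int = Field(default=3, ge=1)
    day_length_s: float = 86_400.0

    @model_validator(mode="after")
    def _check(self) -> "DaySchedule":
        if not (0 <= self.lights_on_s < self.lights_off_s <= self.day_length_s):
            raise ValueError("need 0 <= lights_on < lights_off <= day length")
        return self

    def lights_window(self, day: int) -> tuple[float, float]:
        """Absolute (start, end) of lights-on for a zero-based day index."""
        base = day * self.day_length_s
        return base + self.lights_on_s, base + self.lights_off_s

    @property
    def lights_on_duration_s(self) -> float:
        return self.lights_off_s - self.lights_on_s


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class PlaceAgentState:
    """Softmax place-preference agent over two test perches plus off-perch.

    ``perch_values`` are the valence accumulators for perches 1 and 2;
    ``off_value`` is the fixed attractiveness of everywhere else. Each
    delivered stimulus moves the occupied perch's value toward the
    stimulus valence by ``stimulus_learning_rate``; the asymptotic landing
    logit between perches is therefore ``valence / softmax_temperature``.
    ``dwell_scale`` multiplies the mean bout duration per perch, letting
    occupancy and landing preferences differ.
    """

    perch_values: tuple[float, float] = (0.0, 0.0)
    softmax_temperature: float = 1.0
    mean_bout_s: float = 15.0
    mean_off_s: float = 30.0
    off_value: float = 1.0
    noise_valence: float = _logit(0.86)  # appetitive
    strobe_valence: float = -_logit(0.813)  # aversive
    dwell_scale: tuple[float, float] = (1.0, 1.0)
    stimulus_learning_rate: float = 0.05
    value_decay_per_day: float = 0.5  # overnight forgetting toward neutral

    def __post_init__(self) -> None:
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")
        if not (0 < self.stimulus_learning_rate <= 1):
            raise ValueError("stimulus_learning_rate must be in (0, 1]")
        if not (0 <= self.value_decay_per_day <= 1):
            raise ValueError("value_decay_per_day must be in [0, 1]")

    def overnight(self) -> "PlaceAgentState":
        """Apply one night's forgetting: accumulators shrink toward zero.

        A perch that keeps its contingency re-saturates within minutes the
        next morning; a perch whose contingency ended drifts back to
        neutral over a few days, which is what lets a reversal re-express
        the mirrored preference."""
        keep = 1.0 - self.value_decay_per_day
        return replace(self, perch_values=tuple(v * keep for v in self.perch_values))


def place_choice_probs(place: PlaceAgentState) -> np.ndarray:
    """(p_perch1, p_perch2, p_off); sums to 1."""
    logits = np.array([*place.perch_values, place.off_value]) / place.softmax_temperature
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def calibrated_place_agent(
    kind: Literal["noise", "strobe"],
    target_perch: int,
    landing_prob: float,
    occupancy: float | None = None,
    **overrides,
) -> PlaceAgentState:
    """Place agent whose asymptotic preference matches given group values.

    ``landing_prob`` is the asymptotic probability of choosing the
    *preferred* perch among the two test perches: the stimulated perch for
    noise (appetitive), the non-stimulated perch for strobe (aversive).
    If ``occupancy`` differs from ``landing_prob``, per-perch dwell scales
    are set so time-based occupancy matches it too.
    """
    if not (0.5 < landing_prob < 1.0):
        raise ValueError("landing_prob must express a preference in (0.5, 1)")
    temperature = overrides.get("softmax_temperature", 1.0)
    magnitude = temperature * _logit(landing_prob)
    dwell = [1.0, 1.0]
    if occupancy is not None:
        # occupancy = p*d_pref / (p*d_pref + (1-p)*d_other); solve d_pref.
        d_pref = (occupancy / (1.0 - occupancy)) * ((1.0 - landing_prob) / landing_prob)
        pref_perch = target_perch if kind == "noise" else (3 - target_perch)
        dwell[pref_perch - 1] = d_pref
    kwargs = dict(dwell_scale=tuple(dwell), **overrides)
    if kind == "noise":
        kwargs["noise_valence"] = magnitude
    else:
        kwargs["strobe_valence"] = -magnitude
    return PlaceAgentState(**kwargs)


def simulate_perch_day(
    place: PlaceAgentState,
    schedule: DaySchedule,
    contingency: ContingencyConfig | None,
    day: int,
    seed: int | np.random.Generator,
    bird_id: int = 0,
    collect_stimuli: bool = True,
) -> tuple[list[PerchEvent], list[StimulusEvent], PlaceAgentState]:
    """Simulate one lights-on day of perch behavior with closed-loop feedback.

    The agent repeatedly softmax-chooses perch 1 / perch 2 / off-perch and
    dwells an exponential time. Bouts on the contingency's target perch
    trigger the landing + jittered-repeat stimulus train, and every
    delivered stimulus updates the perch value (applied in closed form per
    bout). No event intersects lights-off. Returns the bout list, the
    stimulus list (empty if ``collect_stimuli`` is false) and the
    end-of-day agent state.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_start, t_end = schedule.lights_window(day)
    values = list(place.perch_values)
    events: list[PerchEvent] = []
    stimuli: list[StimulusEvent] = []

    perch_mode = contingency is not None and contingency.is_perch_mode
    if perch_mode:
        stim_kind = contingency.stimulus.kind
        valence = place.noise_valence if stim_kind == "noise" else place.strobe_valence
        alpha = place.stimulus_learning_rate

    t = t_start
    while t < t_end - 1e-9:
        logits = np.array([*values, place.off_value]) / place.softmax_temperature
        logits -= logits.max()
        w = np.exp(logits)
        loc = rng.choice(3, p=w / w.sum())
        if loc == 2:
            t = min(t + rng.exponential(place.mean_off_s), t_end)
            continue
        dwell = rng.exponential(place.mean_bout_s * place.dwell_scale[loc])
        t_leave = min(t + dwell, t_end)
        if t_leave - t < 1e-6:
            t = t_leave
            continue
        ev = PerchEvent(bird_id=bird_id, day=day, perch_id=loc + 1,
                        t_land_s=t, t_leave_s=t_leave)
        events.append(ev)
        if perch_mode and ev.perch_id == contingency.target_perch:
            onsets = _stimulus_onsets(ev.duration_s, contingency, rng)
            if onsets.size:
                # k identical leaky updates collapse to exponential approach.
                values[loc] = valence + (values[loc] - valence) * (1 - alpha) ** onsets.size
                if collect_stimuli:
                    causes = ["landing"] + ["repeat"] * (onsets.size - 1)
                    stimuli.extend(
                        StimulusEvent(time_s=float(ev.t_land_s + o), kind=stim_kind,
                                      cause=c, source=ev.perch_id,
                                      bird_id=bird_id, day=day)
                        for o, c in zip(onsets, causes)
                    )
        t = t_leave
    return events, stimuli, replace(place, perch_values=(values[0], values[1]))


def generate_singing_epochs(
    schedule: DaySchedule,
    day: int,
    seed: int | np.random.Generator,
    mean_interval_s: float = 90.0,
    mean_epoch_s: float = 4.0,
) -> list[tuple[float, float]]:
    """Song-epoch intervals (first onset to last offset) for one lights-on day.

    Epochs arrive as a Poisson process and last an exponential time;
    used to build the singing/non-singing track for perch sessions. The
    defaults are an arbitrary but fixed singing budget (~4% of the day);
    no published bout statistics constrain them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_start, t_end = schedule.lights_window(day)
    epochs = []
    t = t_start + rng.exponential(mean_interval_s)
    while t < t_end:
        dur = min(rng.exponential(mean_epoch_s) + 0.5, t_end - t)
        epochs.append((t, t + dur))
        t = t + dur + rng.exponential(mean_interval_s)
    return epochs
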
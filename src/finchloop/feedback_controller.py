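"""Stimulus rendering and delivery timing for the four contingencies.

Two stimuli exist, both 75 ms: a band-limited (1.5-8 kHz) noise burst and
a strobe pattern (5 ms LEDs on, 65 ms everything dark, 5 ms LEDs on). A
session runs exactly one of four contingencies: the stimulus is yoked
either to occupancy of a target perch (delivered 1 ms after landing and
then repeatedly at 2 +/- 0.25 Hz while the perch stays occupied) or to
low-pitch renditions of a target syllable (delivered 0-2 ms after the
6 ms pitch-measurement window).
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .audio import AudioBuffer
from .events import PerchEvent, StimulusEvent
from .pitch_contingency import PitchConfig

#: Digital level convention: the physical 88 dB calibration maps to
#: -20 dBFS RMS, i.e. dBFS = dB(level) - FULL_SCALE_DB_OFFSET.
FULL_SCALE_DB_OFFSET = 108.0

STIMULUS_DURATION_MS = 75.0


class StimulusSpec(BaseModel):
    """One feedback stimulus: 75 ms noise burst or 75 ms strobe pattern."""

    model_config = {"frozen": True}

    kind: Literal["noise", "strobe"]
    duration_ms: float = STIMULUS_DURATION_MS
    noise_band_hz: tuple[float, float] = (1500.0, 8000.0)
    noise_level_db: float = 88.0
    strobe_pattern_ms: tuple[float, ...] = (5.0, 65.0, 5.0)

    @model_validator(mode="after")
    def _check(self) -> "StimulusSpec":
        if self.duration_ms != STIMULUS_DURATION_MS:
            raise ValueError(f"stimulus duration is fixed at {STIMULUS_DURATION_MS} ms")
        if self.kind == "strobe" and abs(sum(self.strobe_pattern_ms) - self.duration_ms) > 1e-9:
            raise ValueError(
                f"strobe pattern {self.strobe_pattern_ms} must sum to {self.duration_ms} ms"
            )
        lo, hi = self.noise_band_hz
        if not (0 < lo < hi):
            raise ValueError("noise_band_hz must satisfy 0 < low < high")
        return self


class ContingencyConfig(BaseModel):
    """Which of the four contingencies is active, and its timing parameters.

    ``repeat_rate_hz`` +/- ``repeat_jitter_hz`` is read as each
    inter-stimulus interval having frequency drawn uniformly from the
    +/- band (so the long-run rate converges to the nominal 2 Hz).
    """

    model_config = {"frozen": True}

    mode: Literal["perch_strobe", "perch_noise", "pitch_noise", "pitch_strobe"]
    target_perch: int = 1
    landing_lag_ms: float = 1.0
    repeat_rate_hz: float = 2.0
    repeat_jitter_hz: float = 0.25
    stimulus: StimulusSpec | None = None

    @model_validator(mode="after")
    def _fill_stimulus(self) -> "ContingencyConfig":
        kind = "noise" if self.mode.endswith("noise") else "strobe"
        if self.stimulus is None:
            object.__setattr__(self, "stimulus", StimulusSpec(kind=kind))
        elif self.stimulus.kind != kind:
            raise ValueError(f"mode {self.mode} requires a {kind} stimulus")
        if self.repeat_jitter_hz < 0 or self.repeat_jitter_hz >= self.repeat_rate_hz:
            raise ValueError("repeat jitter must be in [0, repeat_rate)")
        return self

    @property
    def is_perch_mode(self) -> bool:
        return self.mode.startswith("perch")


def render_noise_burst(
    spec: StimulusSpec, sample_rate: int, seed: int | np.random.Generator
) -> AudioBuffer:
    """Synthesize the 75 ms band-limited noise burst.

    White Gaussian noise is band-limited to ``spec.noise_band_hz`` by
    zeroing out-of-band DFT bins (an exact brickwall band-pass, so the
    burst carries no measurable out-of-band energy) and RMS-scaled so
    ``noise_level_db`` maps to digital level per
    :data:`FULL_SCALE_DB_OFFSET`. Deterministic for a fixed seed.
    """
    if spec.kind != "noise":
        raise ValueError("render_noise_burst requires a noise stimulus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    white = rng.standard_normal(n)
    lo, hi = spec.noise_band_hz
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    shaped = np.fft.irfft(spectrum, n=n)
    target_rms = 10.0 ** ((spec.noise_level_db - FULL_SCALE_DB_OFFSET) / 20.0)
    rms = np.sqrt(np.mean(shaped**2))
    if rms > 0:
        shaped = shaped * (target_rms / rms)
    return AudioBuffer(shaped, sample_rate)


def strobe_timeline(spec: StimulusSpec) -> list[tuple[str, float]]:
    """Return the strobe pattern as (state, duration_ms) segments.

    The default is ``[("led_on", 5), ("all_off", 65), ("led_on", 5)]``;
    ambient cage light is restored after the final segment.
    """
    if spec.kind != "strobe":
        raise ValueError("strobe_timeline requires a strobe stimulus")
    states = ["led_on" if i % 2 == 0 else "all_off" for i in range(len(spec.strobe_pattern_ms))]
    return list(zip(states, spec.strobe_pattern_ms))


def _stimulus_onsets(
    bout_duration_s: float, cfg: ContingencyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Onset times (s, relative to landing) of the stimulus train in one bout.

    First onset at the landing lag, then intervals ``1/f`` with
    ``f ~ U(rate - jitter, rate + jitter)``; no onset after the bird leaves.
    """
    t0 = cfg.landing_lag_ms / 1000.0
    if t0 > bout_duration_s:
        return np.empty(0)
    lo = cfg.repeat_rate_hz - cfg.repeat_jitter_hz
    hi = cfg.repeat_rate_hz + cfg.repeat_jitter_hz
    onsets = [np.array([t0])]
    t = t0
    while t <= bout_duration_s:
        n_draw = max(16, int(math.ceil((bout_duration_s - t) * hi)) + 3)
        intervals = 1.0 / rng.uniform(lo, hi, size=n_draw)
        times = t + np.cumsum(intervals)
        keep = times <= bout_duration_s
        onsets.append(times[keep])
        if not keep.all():
            break
        t = times[-1]
    return np.concatenate(onsets)


def perch_stimulus_times(
    bout: PerchEvent, cfg: ContingencyConfig, seed: int | np.random.Generator
) -> list[StimulusEvent]:
    """Stimulus events for one occupancy bout under a perch contingency.

    The first stimulus fires ``landing_lag_ms`` after landing; each later
    inter-onset interval is ``1/f`` with ``f ~ U(rate - jitter, rate +
    jitter)``. No onset occurs after the bird leaves; a bout on a
    non-target perch yields no events.
    """
    if not cfg.is_perch_mode:
        raise ValueError(f"mode {cfg.mode} is not perch-contingent")
    if bout.perch_id != cfg.target_perch:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = _stimulus_onsets(bout.duration_s, cfg, rng)
    causes = ["landing"] + ["repeat"] * (len(onsets) - 1)
    return [
        StimulusEvent(
            time_s=float(bout.t_land_s + o),
            kind=cfg.stimulus.kind,
            cause=c,
            source=bout.perch_id,
            bird_id=bout.bird_id,
            day=bout.day,
        )
        for o, c in zip(onsets, causes)
    ]


def pitch_stimulus_time(
    window_start_s: float,
    outcome: str,
    cfg: ContingencyConfig,
    pitch_cfg: PitchConfig,
    seed: int | np.random.Generator,
    rendition_index: int = 0,
    bird_id: int = 0,
    day: int = 0,
) -> StimulusEvent:
    """Stimulus onset for one hit rendition under a pitch contingency.

    Feedback starts ``lag ~ U(0, distortion_lag_max_ms)`` after the end of
    the 6 ms measurement window. Calling this for an escape is an error.
    """
    if cfg.is_perch_mode:
        raise ValueError(f"mode {cfg.mode} is not pitch-contingent")
    if outcome != "hit":
        raise ValueError("feedback is only delivered on hit renditions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lag_s = rng.uniform(0.0, pitch_cfg.distortion_lag_max_ms / 1000.0)
    t = window_start_s + pitch_cfg.window_ms / 1000.0 + lag_s
    return StimulusEvent(
        time_s=float(t),
        kind=cfg.stimulus.kind,
        cause="pitch_hit",
        source=rendition_index,
        bird_id=bird_id,
        day=day,
    )
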
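"""Online pitch measurement and the adaptive escape contingency.

The pitch of a harmonic-stack syllable is estimated from a single 6 ms
window: the windowed segment is zero-padded, its DFT magnitude is searched
within a band known to contain one harmonic, the peak is refined by
parabolic interpolation, and the peak frequency is divided by the harmonic
number to recover the fundamental.

The contingency keeps an adaptive threshold: initialized to the median
pitch of the final baseline day, then re-examined after every block of 400
renditions and ratcheted to the block median whenever the median has moved
past it in the direction of training. Renditions whose measured pitch falls
on the penalized side of the threshold are "hits" and trigger feedback;
the rest "escape".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .audio import AudioBuffer

#: Renditions per threshold-update block.
THRESHOLD_BLOCK = 400

#: Fixed pitch-measurement window length (ms).
PITCH_WINDOW_MS = 6.0


class SilentWindowError(ValueError):
    """The measurement window contains no signal power."""


class OutOfBandError(ValueError):
    """No spectral peak could be resolved inside the search band."""


class PitchConfig(BaseModel):
    """Parameters of the 6 ms FFT pitch measurement.

    ``harmonic_band_hz`` is the search band, chosen per bird to bracket
    one harmonic (``harmonic_number``) of the target syllable across its
    rendition-to-rendition pitch range. ``fft_oversample`` is the
    zero-padding factor; at 40 kHz the native 6 ms resolution is ~167 Hz,
    and a factor of 64 with parabolic peak refinement brings the error
    below a few Hz. ``distortion_lag_max_ms`` bounds the random lag
    between the end of the window and feedback onset.
    """

    model_config = {"frozen": True}

    window_ms: float = PITCH_WINDOW_MS
    harmonic_band_hz: tuple[float, float] = (1050.0, 1450.0)
    harmonic_number: int = Field(default=2, ge=1)
    fft_oversample: int = Field(default=64, ge=1)
    distortion_lag_max_ms: float = Field(default=2.0, ge=0.0, le=2.0)

    @model_validator(mode="after")
    def _check(self) -> "PitchConfig":
        if self.window_ms != PITCH_WINDOW_MS:
            raise ValueError(f"pitch window is fixed at {PITCH_WINDOW_MS} ms")
        lo, hi = self.harmonic_band_hz
        if not (0.0 < lo < hi):
            raise ValueError("harmonic_band_hz must satisfy 0 < low < high")
        return self


@dataclass(frozen=True)
class ThresholdState:
    """Adaptive contingency threshold with its ratchet history.

    ``direction`` names the penalized side: ``below`` penalizes (and
    thereby drives pitch away from) renditions under the threshold.
    ``history`` records (rendition index, threshold) at initialization and
    after each update decision.
    """

    threshold_hz: float
    direction: Literal["below", "above"] = "below"
    renditions_since_update: int = 0
    block_size: int = THRESHOLD_BLOCK
    history: tuple[tuple[int, float], ...] = field(default_factory=tuple)


def measure_pitch(audio: AudioBuffer, window_start_s: float, cfg: PitchConfig) -> float:
    """Estimate the fundamental from one 6 ms window of a harmonic stack.

    Returns the peak frequency in ``cfg.harmonic_band_hz`` of the
    Hann-windowed, zero-padded DFT magnitude, refined by parabolic
    interpolation and divided by ``cfg.harmonic_number``. Pure function.

    Raises
    ------
    ValueError
        If the window does not lie fully inside the buffer.
    SilentWindowError
        If the window has (numerically) zero power.
    OutOfBandError
        If the search band contains no resolvable DFT bins.
    """
    seg = audio.slice(window_start_s, cfg.window_ms / 1000.0).samples
    if float(np.sum(seg**2)) < 1e-20:
        raise SilentWindowError("pitch window contains no signal power")
    seg = seg - seg.mean()
    windowed = seg * np.hanning(seg.size)
    n_fft = int(seg.size * cfg.fft_oversample)
    spectrum = np.abs(np.fft.rfft(windowed, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / audio.sample_rate)

    lo, hi = cfg.harmonic_band_hz
    in_band = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if in_band.size < 3:
        raise OutOfBandError(f"search band ({lo}, {hi}) Hz resolves <3 DFT bins")
    k = in_band[np.argmax(spectrum[in_band])]
    # Parabolic refinement on log magnitude, guarded at spectrum edges.
    if 0 < k < spectrum.size - 1 and spectrum[k - 1] > 0 and spectrum[k + 1] > 0:
        a, b, c = np.log(spectrum[k - 1 : k + 2])
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    bin_width = audio.sample_rate / n_fft
    peak_hz = (k + delta) * bin_width
    return peak_hz / cfg.harmonic_number


def initialize_threshold(
    baseline_pitches: list[float] | np.ndarray,
    direction: Literal["below", "above"] = "below",
    block_size: int = THRESHOLD_BLOCK,
) -> ThresholdState:
    """Set the initial threshold to the median final-baseline-day pitch.

    An even-length median is the mean of the central pair.
    """
    pitches = np.asarray(baseline_pitches, dtype=float)
    if pitches.size == 0:
        raise ValueError("cannot initialize threshold from an empty baseline")
    med = float(np.median(pitches))
    return ThresholdState(
        threshold_hz=med,
        direction=direction,
        block_size=block_size,
        history=((0, med),),
    )


def update_threshold(state: ThresholdState, last_block_pitches) -> ThresholdState:
    """Apply the per-block median ratchet.

    With ``direction="below"`` the threshold moves up to the median of the
    last block iff that median exceeds the current threshold; it never
    moves down (mirrored for ``direction="above"``). Blocks are tumbling:
    each rendition enters exactly one update.
    """
    pitches = np.asarray(last_block_pitches, dtype=float)
    if pitches.size != state.block_size:
        raise ValueError(
            f"threshold update requires exactly {state.block_size} pitches, "
            f"got {pitches.size}"
        )
    med = float(np.median(pitches))
    if state.direction == "below":
        new_thr = med if med > state.threshold_hz else state.threshold_hz
    else:
        new_thr = med if med < state.threshold_hz else state.threshold_hz
    last_index = state.history[-1][0] if state.history else 0
    return replace(
        state,
        threshold_hz=new_thr,
        renditions_since_update=0,
        history=state.history + ((last_index + state.block_size, new_thr),),
    )


def decide_outcome(pitch_hz: float, state: ThresholdState) -> Literal["hit", "escape"]:
    """Hit iff the pitch lies strictly on the penalized side; ties escape."""
    if state.direction == "below":
        return "hit" if pitch_hz < state.threshold_hz else "escape"
    return "hit" if pitch_hz > state.threshold_hz else "escape"
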
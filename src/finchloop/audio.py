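"""Mono fixed-rate audio container and WAV I/O.

All in-package audio is float64 in [-1, 1] ("full scale"). Files are
written as 16-bit PCM, the format the rest of the pipeline expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 40_000  # Hz


@dataclass(frozen=True)
class AudioBuffer:
    """A mono waveform at a fixed sample rate.

    Parameters
    ----------
    samples
        1-D float array, nominally within [-1, 1] full scale.
    sample_rate
        Samples per second.
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"audio must be mono 1-D, got shape {arr.shape}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate / 2.0

    def rms(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    def slice(self, start_s: float, duration_s: float) -> "AudioBuffer":
        """Extract ``[start_s, start_s + duration_s)``; must lie inside the buffer."""
        i0 = int(round(start_s * self.sample_rate))
        i1 = i0 + int(round(duration_s * self.sample_rate))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(
                f"slice [{start_s:.6f}, {start_s + duration_s:.6f}] s outside "
                f"buffer of {self.duration_s:.6f} s"
            )
        return AudioBuffer(self.samples[i0:i1], self.sample_rate)

    def to_wav(self, path) -> None:
        """Write as 16-bit PCM WAV; samples are clipped to full scale."""
        clipped = np.clip(self.samples, -1.0, 1.0)
        pcm = np.round(clipped * 32767.0).astype(np.int16)
        wavfile.write(path, self.sample_rate, pcm)

    @classmethod
    def from_wav(cls, path) -> "AudioBuffer":
        """Read a mono WAV file (integer PCM is rescaled to [-1, 1])."""
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("only mono WAV files are supported")
        if np.issubdtype(data.dtype, np.integer):
            scale = float(np.iinfo(data.dtype).max)
            samples = data.astype(np.float64) / scale
        else:
            samples = data.astype(np.float64)
        return cls(samples, int(rate))

    @classmethod
    def silence(cls, duration_s: float, sample_rate: int = DEFAULT_SAMPLE_RATE) -> "AudioBuffer":
        return cls(np.zeros(int(round(duration_s * sample_rate))), sample_rate)


def concatenate(buffers: list[AudioBuffer]) -> AudioBuffer:
    if not buffers:
        raise ValueError("nothing to concatenate")
    rates = {b.sample_rate for b in buffers}
    if len(rates) != 1:
        raise ValueError(f"mixed sample rates: {sorted(rates)}")
    return AudioBuffer(np.concatenate([b.samples for b in buffers]), buffers[0].sample_rate)
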
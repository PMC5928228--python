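"""Real-time-style syllable segmentation and target selection.

Song is segmented on the amplitude envelope (2 ms moving RMS, threshold
with hysteresis), then the target syllable is identified either by a
spectral feature in the preceding syllable (band-pass power ratio with a
Butterworth filter) or by a unique inter-onset interval. A programmable
delay of 10-200 ms maps the detection timestamp onto the start of the
6 ms pitch-measurement window inside the target's harmonic stack.

Causality is emulated on recorded buffers; there are no latency
guarantees, only the same decisions a streaming detector would make.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage, signal

from .audio import AudioBuffer

RMS_WINDOW_MS = 2.0
HYSTERESIS = 0.8  # offset threshold as a fraction of the onset threshold


class DetectorConfig(BaseModel):
    """Segmentation and target-matching parameters.

    ``mode`` selects how the target is recognized: ``spectral_feature``
    matches a band-power ratio in the syllable before the target
    (detection timestamp = that syllable's offset); ``inter_onset_interval``
    matches the previous-onset-to-target-onset interval (detection
    timestamp = the target's onset). ``trigger_delay_ms`` then offsets the
    detection timestamp to the start of the pitch window and must lie in
    the hardware-realizable 10-200 ms range.
    """

    model_config = {"frozen": True}

    amp_threshold: float = Field(default=0.05, gt=0, lt=1)
    min_syllable_ms: float = Field(default=15.0, gt=0)
    min_gap_ms: float = Field(default=15.0, gt=0)
    mode: str = "spectral_feature"
    feature_band_hz: tuple[float, float] = (2400.0, 2600.0)
    feature_ratio_threshold: float = Field(default=0.3, gt=0, le=1)
    ioi_target_ms: float = Field(default=140.0, gt=0)
    ioi_tolerance_ms: float = Field(default=10.0, gt=0)
    trigger_delay_ms: float = 100.0
    butter_order: int = Field(default=4, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "DetectorConfig":
        if self.mode not in ("spectral_feature", "inter_onset_interval"):
            raise ValueError(f"unknown detector mode {self.mode!r}")
        if not (10.0 <= self.trigger_delay_ms <= 200.0):
            raise ValueError("trigger_delay_ms must lie in [10, 200] ms")
        lo, hi = self.feature_band_hz
        if not (0 < lo < hi):
            raise ValueError("feature_band_hz must satisfy 0 < low < high")
        return self


@dataclass(frozen=True)
class SyllableSegment:
    onset_s: float
    offset_s: float
    peak_amplitude: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("segment must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class TargetDetection:
    """One matched target rendition and its scheduled pitch window."""

    segment_index: int
    detection_time_s: float
    window_start_s: float


@lru_cache(maxsize=32)
def _bandpass_sos(order: int, lo: float, hi: float, fs: int) -> np.ndarray:
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _envelope(x: np.ndarray, sample_rate: int) -> np.ndarray:
    """Moving-RMS amplitude envelope over a 2 ms window, DC removed."""
    x = x - x.mean()
    k = max(1, int(round(RMS_WINDOW_MS / 1000.0 * sample_rate)))
    # Centered moving average of the squared signal; silence beyond the
    # buffer edges.
    sq = ndimage.uniform_filter1d(x**2, size=k, mode="constant", cval=0.0)
    return np.sqrt(np.clip(sq, 0.0, None))


def segment_syllables(audio: AudioBuffer, cfg: DetectorConfig) -> list[SyllableSegment]:
    """Amplitude-threshold segmentation with hysteresis.

    A segment is a maximal run where the envelope stays above
    ``HYSTERESIS * amp_threshold`` and reaches ``amp_threshold`` at least
    once. Segments closer than ``min_gap_ms`` are merged, then segments
    shorter than ``min_syllable_ms`` are dropped. Silence yields an empty
    list. Idempotent and insensitive to DC offset.
    """
    if audio.n_samples == 0:
        return []
    env = _envelope(audio.samples, audio.sample_rate)
    above_off = env >= HYSTERESIS * cfg.amp_threshold
    if not above_off.any():
        return []
    # Maximal runs of above_off.
    edges = np.diff(above_off.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above_off[0]:
        starts = np.concatenate([[0], starts])
    if above_off[-1]:
        ends = np.concatenate([ends, [above_off.size]])
    runs = [(s, e) for s, e in zip(starts, ends) if env[s:e].max() >= cfg.amp_threshold]
    if not runs:
        return []
    # Merge runs separated by less than min_gap_ms.
    min_gap = cfg.min_gap_ms / 1000.0 * audio.sample_rate
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = cfg.min_syllable_ms / 1000.0 * audio.sample_rate
    sr = audio.sample_rate
    return [
        SyllableSegment(onset_s=s / sr, offset_s=e / sr, peak_amplitude=float(env[s:e].max()))
        for s, e in merged
        if e - s >= min_len
    ]


def match_spectral_feature(segment_audio: AudioBuffer, cfg: DetectorConfig) -> bool:
    """True iff the band-pass power ratio reaches the feature threshold.

    The segment is zero-phase Butterworth band-pass filtered to
    ``feature_band_hz``; the match statistic is filtered power over total
    power. Zero-power segments never match. Pure function.
    """
    x = segment_audio.samples
    if x.size == 0:
        raise ValueError("empty segment")
    total = float(np.sum(x**2))
    if total <= 0.0:
        return False
    lo, hi = cfg.feature_band_hz
    if hi >= segment_audio.nyquist_hz:
        raise ValueError("feature band must lie below Nyquist")
    sos = _bandpass_sos(cfg.butter_order, lo, hi, segment_audio.sample_rate)
    padlen = min(3 * (2 * cfg.butter_order + 1), x.size - 1)
    filtered = signal.sosfiltfilt(sos, x, padlen=padlen)
    ratio = float(np.sum(filtered**2)) / total
    return ratio >= cfg.feature_ratio_threshold


def match_ioi(prev_onset_s: float, this_onset_s: float, cfg: DetectorConfig) -> bool:
    """True iff the onset-to-onset interval matches the template (inclusive)."""
    if this_onset_s <= prev_onset_s:
        raise ValueError("onsets must be increasing")
    ioi_ms = (this_onset_s - prev_onset_s) * 1000.0
    return abs(ioi_ms - cfg.ioi_target_ms) <= cfg.ioi_tolerance_ms


def schedule_target_window(detection_time_s: float, cfg: DetectorConfig) -> float:
    """Start of the 6 ms pitch window: detection time plus the trigger delay."""
    return detection_time_s + cfg.trigger_delay_ms / 1000.0


def detect_targets(audio: AudioBuffer, cfg: DetectorConfig) -> list[TargetDetection]:
    """Segment a buffer and return every matched target rendition.

    In ``spectral_feature`` mode, a segment matching the feature band
    marks the *next* segment as the target, with detection time at the
    matched segment's offset. In ``inter_onset_interval`` mode, a segment
    whose onset interval from its predecessor matches the template is
    itself the target, with detection time at its onset.
    """
    segments = segment_syllables(audio, cfg)
    detections: list[TargetDetection] = []
    if cfg.mode == "spectral_feature":
        for i in range(len(segments) - 1):
            seg = segments[i]
            seg_audio = audio.slice(seg.onset_s, seg.duration_s)
            if match_spectral_feature(seg_audio, cfg):
                t_det = seg.offset_s
                detections.append(
                    TargetDetection(
                        segment_index=i + 1,
                        detection_time_s=t_det,
                        window_start_s=schedule_target_window(t_det, cfg),
                    )
                )
    else:
        for i in range(1, len(segments)):
            if match_ioi(segments[i - 1].onset_s, segments[i].onset_s, cfg):
                t_det = segments[i].onset_s
                detections.append(
                    TargetDetection(
                        segment_index=i,
                        detection_time_s=t_det,
                        window_start_s=schedule_target_window(t_det, cfg),
                    )
                )
    return detections
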
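"""End-to-end closed-loop sessions for the four contingencies.

A session couples the synthetic bird to the real-time machinery day by
day: generate behavior -> detect -> decide -> deliver stimuli -> update
agents -> log. Pitch sessions run the full DSP path per rendition (motif
synthesis, amplitude segmentation, feature matching, delayed 6 ms FFT
pitch measurement) against the ratcheting threshold; perch sessions run
the softmax place agent against the landing + jittered-repeat stimulus
train. The loop advances at bout/rendition granularity — audio is
synthesized per rendition rather than streamed, which keeps a multi-day
multi-bird experiment at desk scale.

Everything is a pure function of the configuration and its master seed;
per-(bird, day, stream) child generators make each day independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import behavior_metrics as bm
from .audio import DEFAULT_SAMPLE_RATE
from .events import (
    RenditionRecord,
    StimulusEvent,
    perch_events_to_frame,
    renditions_to_frame,
    stimulus_events_to_frame,
    write_perch_csv,
    write_renditions_jsonl,
)
from .feedback_controller import ContingencyConfig, pitch_stimulus_time
from .pitch_contingency import (
    PitchConfig,
    decide_outcome,
    initialize_threshold,
    update_threshold,
)
from .syllable_detector import DetectorConfig, detect_targets
from .synthetic_bird import (
    DaySchedule,
    MotifSpec,
    PlaceAgentState,
    VocalAgentState,
    default_motif,
    generate_singing_epochs,
    make_rng,
    simulate_perch_day,
    synthesize_motif,
    vocal_update,
)

# Per-(bird, day) random stream tags.
_STREAM_SONG, _STREAM_PERCH, _STREAM_SINGING = 0, 1, 2


class SessionConfig(BaseModel):
    """One experiment: birds x days under a single contingency.

    ``reversal`` is (day index, new target perch) and is only meaningful
    in perch modes; pitch modes require the full >= 5 day baseline before
    feedback starts.
    """

    model_config = {"arbitrary_types_allowed": True}

    birds: int = Field(default=5, ge=1)
    schedule: DaySchedule = DaySchedule()
    contingency: ContingencyConfig
    detector: DetectorConfig = DetectorConfig()
    pitch: PitchConfig = PitchConfig()
    motif: MotifSpec = Field(default_factory=default_motif)
    vocal: VocalAgentState = VocalAgentState()
    place: PlaceAgentState = PlaceAgentState()
    baseline_days: int = Field(default=5, ge=0)
    contingency_days: int = Field(default=4, ge=1)
    renditions_per_day: int = Field(default=400, ge=1)
    reversal: tuple[int, int] | None = None
    generate_singing: bool = True
    log_stimuli: bool = True
    stop_when_up_by_hz: float | None = None
    sample_rate: int = DEFAULT_SAMPLE_RATE
    master_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SessionConfig":
        if not self.contingency.is_perch_mode and self.baseline_days < 5:
            raise ValueError("pitch contingencies require >= 5 baseline days")
        if self.reversal is not None:
            if self.contingency.is_perch_mode is False:
                raise ValueError("contingency reversal applies to perch modes only")
            day, perch = self.reversal
            if perch not in (1, 2):
                raise ValueError("reversal perch must be 1 or 2")
            if not (0 < day < self.contingency_days):
                raise ValueError("reversal day must fall inside the session")
        return self


@dataclass
class SessionResult:
    """All logs and summaries of one session.

    Re-running :func:`run_session` with the same config reproduces every
    table bit-identically (verifiable via :meth:`checksums`).
    """

    config: SessionConfig
    perch_events: pd.DataFrame
    stimulus_events: pd.DataFrame
    renditions: pd.DataFrame
    metrics: pd.DataFrame
    stats: dict
    condition_by_day: dict[int, str]
    singing_tracks: dict

    def checksums(self) -> dict[str, str]:
        out = {}
        for name in ("perch_events", "stimulus_events", "renditions", "metrics"):
            df: pd.DataFrame = getattr(self, name)
            out[name] = hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
        return out

    def summary(self) -> str:
        lines = [f"mode: {self.config.contingency.mode}", f"birds: {self.config.birds}"]
        for key, val in self.stats.items():
            lines.append(f"{key}: {val}")
        return "\n".join(lines)

    def to_dir(self, out_dir) -> None:
        """Write logs, metrics, stats, config and a checksum manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_perch_csv(self.perch_events, out / "perch_events.csv")
        self.stimulus_events.to_csv(out / "stimulus_events.csv", index=False)
        write_renditions_jsonl(self.renditions, out / "renditions.jsonl")
        self.metrics.to_csv(out / "metrics.csv", index=False)
        with open(out / "stats.json", "w") as fh:
            json.dump(_jsonify(self.stats), fh, indent=2)
        with open(out / "config.json", "w") as fh:
            fh.write(self.config.model_dump_json(indent=2))
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.checksums(), fh, indent=2)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Pitch-contingent sessions
# ---------------------------------------------------------------------------


def measure_rendition(
    true_pitch_hz: float,
    motif: MotifSpec,
    detector: DetectorConfig,
    pitch_cfg: PitchConfig,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
):
    """Run the DSP path on one synthesized motif rendition.

    Returns (measured_pitch_hz, window_start_s within the motif) or None
    if the detector failed to single out the target syllable.
    """
    audio, _spans = synthesize_motif(motif, true_pitch_hz, sample_rate)
    detections = [
        d for d in detect_targets(audio, detector) if d.segment_index == motif.target_index
    ]
    if len(detections) != 1:
        return None
    det = detections[0]
    if det.window_start_s + pitch_cfg.window_ms / 1000.0 > audio.duration_s:
        return None
    from .pitch_contingency import measure_pitch

    return measure_pitch(audio, det.window_start_s, pitch_cfg), det.window_start_s


def _run_pitch_session(cfg: SessionConfig) -> SessionResult:
    records: list[RenditionRecord] = []
    stimuli: list[StimulusEvent] = []
    stim_kind = cfg.contingency.stimulus.kind
    duration = cfg.schedule.lights_on_duration_s

    for bird in range(cfg.birds):
        vocal = cfg.vocal
        final_baseline_measured: list[float] = []

        for day in range(cfg.baseline_days):
            rng = make_rng(cfg.master_seed, bird, day, _STREAM_SONG)
            t0, _ = cfg.schedule.lights_window(day)
            pitches = rng.normal(vocal.pitch_mean_hz, vocal.pitch_sd_hz,
                                 cfg.renditions_per_day)
            is_final_baseline = day == cfg.baseline_days - 1
            for r, p in enumerate(pitches):
                t = t0 + (r + 0.5) * duration / cfg.renditions_per_day
                if is_final_baseline:
                    m = measure_rendition(float(p), cfg.motif, cfg.detector,
                                          cfg.pitch, cfg.sample_rate)
                    measured = m[0] if m is not None else float("nan")
                    if m is not None:
                        final_baseline_measured.append(measured)
                else:
                    measured = float(p)  # logged without the DSP path
                records.append(
                    RenditionRecord(bird_id=bird, day=day, phase="baseline", time_s=t,
                                    pitch_hz=measured, true_pitch_hz=float(p),
                                    threshold_hz=float("nan"),
                                    outcome="escape", stimulus="none")
                )
            if vocal.daily_drift_hz:
                vocal = dataclasses.replace(
                    vocal, pitch_mean_hz=vocal.pitch_mean_hz + vocal.daily_drift_hz
                )

        thr = initialize_threshold(final_baseline_measured)
        # "up" criterion is relative to the measured baseline
        baseline_mean = float(np.mean(final_baseline_measured))
        block: list[float] = []
        for cd in range(cfg.contingency_days):
            day = cfg.baseline_days + cd
            rng = make_rng(cfg.master_seed, bird, day, _STREAM_SONG)
            t0, _ = cfg.schedule.lights_window(day)
            day_pitches = []
            for r in range(cfg.renditions_per_day):
                p = float(rng.normal(vocal.pitch_mean_hz, vocal.pitch_sd_hz))
                t = t0 + (r + 0.5) * duration / cfg.renditions_per_day
                m = measure_rendition(p, cfg.motif, cfg.detector, cfg.pitch,
                                      cfg.sample_rate)
                if m is None:
                    continue  # missed rendition: no measurement, no feedback
                measured, window_rel = m
                outcome = decide_outcome(measured, thr)
                if outcome == "hit":
                    ev = pitch_stimulus_time(
                        t + window_rel, outcome, cfg.contingency, cfg.pitch, rng,
                        rendition_index=r, bird_id=bird, day=day,
                    )
                    if cfg.log_stimuli:
                        stimuli.append(ev)
                    vocal = vocal_update(vocal, p, outcome, stim_kind, thr.direction)
                records.append(
                    RenditionRecord(bird_id=bird, day=day, phase="contingency",
                                    time_s=t, pitch_hz=measured, true_pitch_hz=p,
                                    threshold_hz=thr.threshold_hz, outcome=outcome,
                                    stimulus=stim_kind if outcome == "hit" else "none")
                )
                block.append(measured)
                day_pitches.append(measured)
                if len(block) == thr.block_size:
                    thr = update_threshold(thr, block)
                    block = []
            if vocal.daily_drift_hz:
                vocal = dataclasses.replace(
                    vocal, pitch_mean_hz=vocal.pitch_mean_hz + vocal.daily_drift_hz
                )
            if (
                cfg.stop_when_up_by_hz is not None
                and day_pitches
                and np.mean(day_pitches) >= baseline_mean + cfg.stop_when_up_by_hz
            ):
                break

    renditions = renditions_to_frame(records)
    contingency_rows = renditions[renditions["phase"] == "contingency"]
    per_bird_delta = [
        bm.daily_pitch_change(contingency_rows[contingency_rows["bird_id"] == b])
        for b in range(cfg.birds)
    ]
    stats: dict = {"per_bird_delta_hz_per_day": per_bird_delta}
    deltas = np.asarray(per_bird_delta, dtype=float)
    deltas = deltas[~np.isnan(deltas)]
    stats["group_delta_hz_per_day"] = float(np.mean(deltas)) if deltas.size else float("nan")
    if deltas.size >= 2:
        stats["delta_t_vs_zero"] = bm.one_sample_t(deltas, null_mean=0.0)

    condition_by_day = {
        d: "baseline" if d < cfg.baseline_days else cfg.contingency.mode
        for d in range(cfg.baseline_days + cfg.contingency_days)
    }
    metrics = bm.compute_metrics(
        perch_events=perch_events_to_frame([]),
        schedule=cfg.schedule,
        renditions=contingency_rows,
        condition_by_day=condition_by_day,
    )
    return SessionResult(
        config=cfg,
        perch_events=perch_events_to_frame([]),
        stimulus_events=stimulus_events_to_frame(stimuli),
        renditions=renditions,
        metrics=metrics,
        stats=stats,
        condition_by_day=condition_by_day,
        singing_tracks={},
    )


# ---------------------------------------------------------------------------
# Perch-contingent sessions
# ---------------------------------------------------------------------------


def _run_perch_session(cfg: SessionConfig) -> SessionResult:
    all_events = []
    all_stimuli: list[StimulusEvent] = []
    tracks: dict[tuple[int, int], bm.SingingStateTrack] = {}
    condition_by_day: dict[int, str] = {}
    kind = cfg.contingency.stimulus.kind

    for bird in range(cfg.birds):
        place = cfg.place
        for day in range(cfg.contingency_days):
            if day > 0:
                place = place.overnight()
            contingency = cfg.contingency
            if cfg.reversal is not None and day >= cfg.reversal[0]:
                contingency = cfg.contingency.model_copy(
                    update={"target_perch": cfg.reversal[1]}
                )
            condition_by_day[day] = f"P{contingency.target_perch}_{kind}"
            rng = make_rng(cfg.master_seed, bird, day, _STREAM_PERCH)
            events, stims, place = simulate_perch_day(
                place, cfg.schedule, contingency, day, rng,
                bird_id=bird, collect_stimuli=cfg.log_stimuli,
            )
            all_events.extend(events)
            all_stimuli.extend(stims)
            if cfg.generate_singing:
                epochs = generate_singing_epochs(
                    cfg.schedule, day, make_rng(cfg.master_seed, bird, day, _STREAM_SINGING)
                )
                tracks[(bird, day)] = bm.SingingStateTrack.from_song_epochs(
                    epochs, cfg.schedule.lights_window(day)
                )

    perch_events = perch_events_to_frame(all_events)
    metrics = bm.compute_metrics(
        perch_events=perch_events,
        schedule=cfg.schedule,
        condition_by_day=condition_by_day,
        singing_tracks=tracks or None,
    )

    stats: dict = {}
    if not metrics.empty:
        conditions = sorted(metrics["condition"].unique())
        for cond in conditions:
            sub = metrics[metrics["condition"] == cond]
            per_bird_occ = sub.groupby("bird_id")["perch1_occupancy"].mean().to_numpy()
            per_bird_land = sub.groupby("bird_id")["perch1_landing_rate"].mean().to_numpy()
            stats[f"{cond}_mean_p1_occupancy"] = float(np.nanmean(per_bird_occ))
            stats[f"{cond}_mean_p1_landing_rate"] = float(np.nanmean(per_bird_land))
            if np.sum(~np.isnan(per_bird_occ)) >= 2:
                stats[f"{cond}_occupancy_t_vs_0.5"] = bm.one_sample_t(per_bird_occ)
        if cfg.reversal is not None and len(conditions) == 2:
            a = metrics[metrics["condition"] == conditions[0]]
            b = metrics[metrics["condition"] == conditions[1]]
            stats["reversal_occupancy_t"] = bm.two_sample_t(
                a.groupby("bird_id")["perch1_occupancy"].mean(),
                b.groupby("bird_id")["perch1_occupancy"].mean(),
            )
        # the singing-split ANOVA needs both contingency conditions observed
        if tracks and metrics["condition"].nunique() == 2:
            stats["singing_anova"] = singing_split_anova(metrics)

    return SessionResult(
        config=cfg,
        perch_events=perch_events,
        stimulus_events=stimulus_events_to_frame(all_stimuli),
        renditions=renditions_to_frame([]),
        metrics=metrics,
        stats=stats,
        condition_by_day=condition_by_day,
        singing_tracks=tracks,
    )


def singing_split_anova(metrics: pd.DataFrame) -> bm.AnovaResult:
    """Two-way ANOVA of perch-1 occupancy: contingency condition x singing state.

    Bird-days are the units; each contributes one singing and one
    non-singing occupancy row.
    """
    rows = []
    for r in metrics.itertuples():
        for state, col in (
            ("singing", "singing_occupancy_p1"),
            ("non_singing", "nonsinging_occupancy_p1"),
        ):
            rows.append(
                {
                    "occupancy": getattr(r, col),
                    "condition": r.condition,
                    "singing_state": state,
                }
            )
    return bm.two_way_anova(pd.DataFrame(rows))


def run_session(cfg: SessionConfig) -> SessionResult:
    """Run one closed-loop session; deterministic under ``cfg.master_seed``."""
    if cfg.contingency.is_perch_mode:
        return _run_perch_session(cfg)
    return _run_pitch_session(cfg)


# ---------------------------------------------------------------------------
# The four-experiment suite
# ---------------------------------------------------------------------------


def reproduce_experiment_suite(
    out_dir=None,
    master_seed: int = 0,
    schedule: DaySchedule | None = None,
    renditions_per_day: int = 400,
    baseline_days: int = 5,
    pitch_days: int = 4,
    target_hz_per_day: float = 8.8,
    noise_occupancy: float = 0.86,
    strobe_landing: float = 0.813,
    strobe_occupancy: float = 0.737,
) -> dict:
    """Run all four contingencies plus the two singing-split analyses.

    Produces one result per contingency — perch strobe and perch noise
    with mid-session reversal, pitch noise, pitch strobe — with agents
    calibrated to the group effect sizes the real experiments reported,
    and the two singing-state ANOVAs from the perch sessions. Writing to
    ``out_dir`` is optional; identical seeds reproduce identical
    checksums.
    """
    from .synthetic_bird import calibrated_place_agent, calibrated_vocal_agent

    results: dict = {}
    sched_strobe = schedule or DaySchedule(n_days=8)
    results["perch_strobe"] = run_session(
        SessionConfig(
            birds=6,
            schedule=sched_strobe,
            contingency=ContingencyConfig(mode="perch_strobe", target_perch=1),
            place=calibrated_place_agent("strobe", 1, strobe_landing, strobe_occupancy),
            baseline_days=0,
            contingency_days=8,
            reversal=(4, 2),
            master_seed=master_seed,
        )
    )
    sched_noise = schedule or DaySchedule(n_days=6)
    results["perch_noise"] = run_session(
        SessionConfig(
            birds=5,
            schedule=sched_noise,
            contingency=ContingencyConfig(mode="perch_noise", target_perch=1),
            place=calibrated_place_agent("noise", 1, noise_occupancy, noise_occupancy),
            baseline_days=0,
            contingency_days=6,
            reversal=(3, 2),
            master_seed=master_seed + 1,
        )
    )
    vocal = calibrated_vocal_agent(
        target_hz_per_day,
        renditions_per_day=renditions_per_day,
        contingency_days=pitch_days,
    )
    results["pitch_noise"] = run_session(
        SessionConfig(
            birds=5,
            contingency=ContingencyConfig(mode="pitch_noise"),
            vocal=vocal,
            baseline_days=baseline_days,
            contingency_days=pitch_days,
            renditions_per_day=renditions_per_day,
            master_seed=master_seed + 2,
        )
    )
    results["pitch_strobe"] = run_session(
        SessionConfig(
            birds=5,
            contingency=ContingencyConfig(mode="pitch_strobe"),
            vocal=vocal,  # visual coupling is zero: strobe cannot move pitch
            baseline_days=baseline_days,
            contingency_days=pitch_days,
            renditions_per_day=renditions_per_day,
            master_seed=master_seed + 3,
        )
    )
    results["singing_split_strobe"] = results["perch_strobe"].stats.get("singing_anova")
    results["singing_split_noise"] = results["perch_noise"].stats.get("singing_anova")

    if out_dir is not None:
        out = Path(out_dir)
        for name in ("perch_strobe", "perch_noise", "pitch_noise", "pitch_strobe"):
            results[name].to_dir(out / name)
        summary = {
            name: _jsonify(results[name].stats)
            for name in ("perch_strobe", "perch_noise", "pitch_noise", "pitch_strobe")
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return results
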
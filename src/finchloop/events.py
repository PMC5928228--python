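"""Event records shared across the pipeline.

Three record types flow between modules: perch occupancy intervals from
beam-break sensors, delivered feedback stimuli, and per-rendition pitch
records from the song contingency. Each has a canonical tabular form
(:func:`*_to_frame`) and plain-text serialization (CSV for perch events,
JSONL for rendition records) so externally supplied logs can enter the
analysis stage.

Times are seconds since session start; ``day`` is the zero-based day index.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Literal

import pandas as pd

PERCH_EVENT_COLUMNS = ["bird_id", "day", "perch_id", "t_land_s", "t_leave_s"]
STIMULUS_EVENT_COLUMNS = ["bird_id", "day", "time_s", "kind", "cause", "source"]
RENDITION_COLUMNS = [
    "bird_id",
    "day",
    "phase",
    "time_s",
    "pitch_hz",
    "true_pitch_hz",
    "threshold_hz",
    "outcome",
    "stimulus",
]


@dataclass(frozen=True)
class PerchEvent:
    """One occupancy bout on a test perch (land to leave)."""

    bird_id: int
    day: int
    perch_id: int
    t_land_s: float
    t_leave_s: float

    def __post_init__(self) -> None:
        if self.t_leave_s <= self.t_land_s:
            raise ValueError("bout must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.t_leave_s - self.t_land_s


@dataclass(frozen=True)
class StimulusEvent:
    """One delivered feedback stimulus (onset time).

    ``cause`` records which branch of the controller fired: ``landing``
    (perch touch-down), ``repeat`` (sustained occupancy), or ``pitch_hit``
    (low-pitch rendition). ``source`` is the perch id for perch causes and
    the rendition index for pitch causes.
    """

    time_s: float
    kind: Literal["noise", "strobe"]
    cause: Literal["landing", "repeat", "pitch_hit"]
    source: int
    bird_id: int = 0
    day: int = 0


@dataclass(frozen=True)
class RenditionRecord:
    """One production of the target syllable and the decision made on it.

    ``pitch_hz`` is the pitch the online measurement returned;
    ``true_pitch_hz`` is the generator's ground truth (NaN for external
    recordings). A rendition is a ``hit`` iff its measured pitch fell on
    the penalized side of the threshold.
    """

    bird_id: int
    day: int
    phase: Literal["baseline", "contingency"]
    time_s: float
    pitch_hz: float
    true_pitch_hz: float
    threshold_hz: float
    outcome: Literal["hit", "escape"]
    stimulus: Literal["noise", "strobe", "none"]


def perch_events_to_frame(events: Iterable[PerchEvent]) -> pd.DataFrame:
    rows = [asdict(e) for e in events]
    return pd.DataFrame(rows, columns=PERCH_EVENT_COLUMNS)


def stimulus_events_to_frame(events: Iterable[StimulusEvent]) -> pd.DataFrame:
    rows = [asdict(e) for e in events]
    return pd.DataFrame(rows, columns=STIMULUS_EVENT_COLUMNS)


def renditions_to_frame(records: Iterable[RenditionRecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    return pd.DataFrame(rows, columns=RENDITION_COLUMNS)


def write_perch_csv(events: Iterable[PerchEvent] | pd.DataFrame, path) -> None:
    df = events if isinstance(events, pd.DataFrame) else perch_events_to_frame(events)
    df.to_csv(path, index=False)


def read_perch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PERCH_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"perch event CSV missing columns: {sorted(missing)}")
    return df


def write_renditions_jsonl(records: Iterable[RenditionRecord] | pd.DataFrame, path) -> None:
    df = records if isinstance(records, pd.DataFrame) else renditions_to_frame(records)
    with open(path, "w") as fh:
        for row in df.to_dict(orient="records"):
            fh.write(json.dumps(row) + "\n")


def read_renditions_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    return pd.DataFrame(rows, columns=RENDITION_COLUMNS)
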
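"""Behavioral read-outs and their statistical battery.

Landing rate and occupancy express place preference as the fraction of
test-perch landings / test-perch time attributed to one perch, with
lights-off periods excluded from every denominator. Occupancy can be
conditioned on singing state, where "singing" runs from 1 s of silence
before a song onset to 1 s of silence after the offset and all other
lights-on time is "non-singing". Vocal learning is summarized as the mean
day-to-day change in daily mean target-syllable pitch.

Undefined quantities (zero denominators, too few days) propagate as NaN,
never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .synthetic_bird import DaySchedule

TEST_PERCHES = (1, 2)

#: A day must have at least this many renditions to enter the
#: pitch-change estimate.
MIN_RENDITIONS_PER_DAY = 20


# ---------------------------------------------------------------------------
# Interval utilities and the singing-state track
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


@dataclass(frozen=True)
class SingingStateTrack:
    """Singing/non-singing intervals tiling one lights-on day."""

    intervals: tuple[tuple[float, float, str], ...]

    @classmethod
    def from_song_epochs(
        cls,
        epochs: list[tuple[float, float]],
        lights_window: tuple[float, float],
        pad_s: float = 1.0,
    ) -> "SingingStateTrack":
        """Build the track from song-epoch (first onset, last offset) intervals.

        Each epoch is padded by 1 s on both sides; overlapping padded
        epochs merge (so gaps under 2 s never split a singing interval),
        and the complement within the lights-on window is non-singing.
        """
        t0, t1 = lights_window
        padded = [
            (max(t0, s - pad_s), min(t1, e + pad_s)) for s, e in epochs if e > t0 and s < t1
        ]
        singing = _merge_intervals(padded)
        out: list[tuple[float, float, str]] = []
        cursor = t0
        for s, e in singing:
            if s > cursor:
                out.append((cursor, s, "non_singing"))
            out.append((s, e, "singing"))
            cursor = e
        if cursor < t1:
            out.append((cursor, t1, "non_singing"))
        return cls(tuple(out))

    def validate_tiling(self, lights_window: tuple[float, float]) -> None:
        t0, t1 = lights_window
        if not self.intervals:
            raise ValueError("empty singing-state track")
        cursor = t0
        for s, e, _ in self.intervals:
            if abs(s - cursor) > 1e-6 or e <= s:
                raise ValueError("singing-state track does not tile the day")
            cursor = e
        if abs(cursor - t1) > 1e-6:
            raise ValueError("singing-state track does not reach lights-off")

    def state_duration(self, state: str) -> float:
        return sum(e - s for s, e, st in self.intervals if st == state)


# ---------------------------------------------------------------------------
# Place-preference metrics
# ---------------------------------------------------------------------------


def _day_events(events: pd.DataFrame, day: int) -> pd.DataFrame:
    df = events[(events["day"] == day) & events["perch_id"].isin(TEST_PERCHES)]
    return df


def landing_rate(
    events: pd.DataFrame, day: int, perch_id: int, schedule: DaySchedule
) -> float:
    """Fraction of lights-on test-perch landings that were on ``perch_id``.

    NaN when no landings occurred (missing, not zero preference).
    """
    t0, t1 = schedule.lights_window(day)
    df = _day_events(events, day)
    df = df[(df["t_land_s"] >= t0) & (df["t_land_s"] < t1)]
    total = len(df)
    if total == 0:
        return float("nan")
    return float((df["perch_id"] == perch_id).sum() / total)


def occupancy(
    events: pd.DataFrame, day: int, perch_id: int, schedule: DaySchedule
) -> float:
    """Fraction of lights-on test-perch time spent on ``perch_id``.

    Each bout is clipped to the lights-on window before its duration
    counts. NaN when no test-perch time exists.
    """
    t0, t1 = schedule.lights_window(day)
    df = _day_events(events, day)
    if df.empty:
        return float("nan")
    clipped = (df["t_leave_s"].clip(upper=t1) - df["t_land_s"].clip(lower=t0)).clip(lower=0.0)
    total = float(clipped.sum())
    if total <= 0.0:
        return float("nan")
    on_perch = float(clipped[df["perch_id"] == perch_id].sum())
    return on_perch / total


def split_by_singing(
    events: pd.DataFrame,
    track: SingingStateTrack,
    day: int,
    perch_id: int,
    schedule: DaySchedule,
) -> tuple[float, float]:
    """(singing, non-singing) occupancy of ``perch_id`` for one day.

    Each bout's lights-on duration is apportioned to states by interval
    intersection; within each state, occupancy is perch time over
    test-perch time. States with no test-perch time yield NaN.
    """
    window = schedule.lights_window(day)
    track.validate_tiling(window)
    df = _day_events(events, day)
    time_on = {"singing": 0.0, "non_singing": 0.0}
    time_total = {"singing": 0.0, "non_singing": 0.0}
    for row in df.itertuples():
        b0 = max(row.t_land_s, window[0])
        b1 = min(row.t_leave_s, window[1])
        if b1 <= b0:
            continue
        for s, e, state in track.intervals:
            d = _overlap(b0, b1, s, e)
            if d > 0:
                time_total[state] += d
                if row.perch_id == perch_id:
                    time_on[state] += d
    out = []
    for state in ("singing", "non_singing"):
        out.append(time_on[state] / time_total[state] if time_total[state] > 0 else float("nan"))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Vocal metrics
# ---------------------------------------------------------------------------


def daily_pitch_change(
    renditions: pd.DataFrame, min_renditions: int = MIN_RENDITIONS_PER_DAY
) -> float:
    """Mean over consecutive-day pairs of the change in daily mean pitch (Hz/day).

    Days with fewer than ``min_renditions`` renditions are excluded; only
    adjacent qualifying days (d, d+1) form pairs. NaN with fewer than two
    qualifying days or no adjacent pair.
    """
    if renditions.empty:
        return float("nan")
    counts = renditions.groupby("day")["pitch_hz"].count()
    means = renditions.groupby("day")["pitch_hz"].mean()
    qualifying = counts[counts >= min_renditions].index
    means = means.loc[qualifying].sort_index()
    if len(means) < 2:
        return float("nan")
    diffs = [
        means[d + 1] - means[d] for d in means.index if d + 1 in means.index
    ]
    if not diffs:
        return float("nan")
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero-variance sample


def one_sample_t(values, null_mean: float = 0.5) -> TTestResult:
    """Classical one-sample t test against a null mean (two-sided).

    A zero-variance sample is degenerate: t=0, p=1 when the common value
    equals the null mean, otherwise t=+/-inf with p=0, flagged.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("one-sample t test needs at least 2 values")
    if np.ptp(x) == 0.0:
        if x[0] == null_mean:
            return TTestResult(t=0.0, p=1.0, df=x.size - 1, degenerate=True)
        sign = 1.0 if x[0] > null_mean else -1.0
        return TTestResult(t=sign * float("inf"), p=0.0, df=x.size - 1, degenerate=True)
    res = stats.ttest_1samp(x, popmean=null_mean)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=x.size - 1)


def two_sample_t(a, b) -> TTestResult:
    """Unpaired two-sample t test with pooled variance (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t test needs at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=a.size + b.size - 2)


@dataclass(frozen=True)
class AnovaResult:
    f_condition: float
    f_state: float
    f_interaction: float
    df_num: int
    df_den: int
    p_condition: float
    p_state: float
    p_interaction: float


def two_way_anova(
    table: pd.DataFrame,
    response: str = "occupancy",
    factor_a: str = "condition",
    factor_b: str = "singing_state",
) -> AnovaResult:
    """Two-way ANOVA with interaction over two two-level factors.

    Type II sums of squares, accommodating unbalanced cells; the units
    are the rows supplied (bird-days in this pipeline). Empty cells are
    an error naming the cell.
    """
    df = table.dropna(subset=[response]).copy()
    levels_a = df[factor_a].unique()
    levels_b = df[factor_b].unique()
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("both factors must have exactly two observed levels")
    for la in levels_a:
        for lb in levels_b:
            if df[(df[factor_a] == la) & (df[factor_b] == lb)].empty:
                raise ValueError(f"empty ANOVA cell: {factor_a}={la!r}, {factor_b}={lb!r}")
    model = smf.ols(f"{response} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    key_a = f"C({factor_a})"
    key_b = f"C({factor_b})"
    key_ab = f"{key_a}:{key_b}"
    return AnovaResult(
        f_condition=float(aov.loc[key_a, "F"]),
        f_state=float(aov.loc[key_b, "F"]),
        f_interaction=float(aov.loc[key_ab, "F"]),
        df_num=int(aov.loc[key_a, "df"]),
        df_den=int(aov.loc["Residual", "df"]),
        p_condition=float(aov.loc[key_a, "PR(>F)"]),
        p_state=float(aov.loc[key_b, "PR(>F)"]),
        p_interaction=float(aov.loc[key_ab, "PR(>F)"]),
    )


# ---------------------------------------------------------------------------
# Per-bird-day metrics table
# ---------------------------------------------------------------------------


def compute_metrics(
    perch_events: pd.DataFrame,
    schedule: DaySchedule,
    renditions: pd.DataFrame | None = None,
    condition_by_day: dict[int, str] | None = None,
    singing_tracks: dict[tuple[int, int], SingingStateTrack] | None = None,
) -> pd.DataFrame:
    """Assemble the per-bird per-day metrics table.

    One row per (bird, day) with perch-1 landing rate and occupancy,
    singing/non-singing perch-1 occupancy (where a track is supplied),
    daily mean pitch, and the bird-level pitch change per day. All
    probabilities lie in [0, 1] or are NaN; lights-off never enters a
    denominator.
    """
    birds = set()
    if not perch_events.empty:
        birds |= set(perch_events["bird_id"].unique())
    if renditions is not None and not renditions.empty:
        birds |= set(renditions["bird_id"].unique())
    rows = []
    for bird in sorted(birds):
        ev = (
            perch_events[perch_events["bird_id"] == bird]
            if not perch_events.empty
            else perch_events
        )
        rend = (
            renditions[renditions["bird_id"] == bird]
            if renditions is not None and not renditions.empty
            else None
        )
        delta = daily_pitch_change(rend) if rend is not None else float("nan")
        days = set()
        if not ev.empty:
            days |= set(ev["day"].unique())
        if rend is not None and not rend.empty:
            days |= set(rend["day"].unique())
        for day in sorted(days):
            sing_p1 = nonsing_p1 = float("nan")
            if singing_tracks and (bird, day) in singing_tracks:
                sing_p1, nonsing_p1 = split_by_singing(
                    ev, singing_tracks[(bird, day)], day, 1, schedule
                )
            mean_pitch = float("nan")
            if rend is not None and not rend.empty:
                day_pitches = rend.loc[rend["day"] == day, "pitch_hz"]
                if len(day_pitches):
                    mean_pitch = float(day_pitches.mean())
            rows.append(
                {
                    "bird_id": bird,
                    "day": day,
                    "condition": (condition_by_day or {}).get(day, ""),
                    "perch1_landing_rate": landing_rate(ev, day, 1, schedule)
                    if not ev.empty
                    else float("nan"),
                    "perch1_occupancy": occupancy(ev, day, 1, schedule)
                    if not ev.empty
                    else float("nan"),
                    "singing_occupancy_p1": sing_p1,
                    "nonsinging_occupancy_p1": nonsing_p1,
                    "mean_pitch_hz": mean_pitch,
                    "delta_pitch_hz_per_day": delta,
                }
            )
    return pd.DataFrame(rows)
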
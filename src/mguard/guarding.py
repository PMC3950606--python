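"""Mate-guarding episode segmentation and daily/period summaries.

A male is mate-guarding (MG) a female when he follows her at a distance
of <= 10 m for more than five consecutive minutes, i.e. an episode opens
at the first minute of a run of at least six consecutive qualifying
1-minute scans. Once open, the episode tolerates up to two consecutive
non-qualifying minutes (female > 10 m away, follow lost, missing
distance flag, or a missing scan row); a third consecutive such minute
closes it, with the end back-dated to the last qualifying minute.
Switching to a different female closes the current episode and opens a
new one once the new female accumulates her own six-minute run.

Days on which MG occupies more than 50 % of observation time are
"extensive" MG days; maximal runs of consecutive extensive days form MG
periods. Calendar days with no observation do not break a period (groups
were not followed every day), but only observed extensive days count
toward its length.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

GRACE_MINUTES = 2  # non-qualifying minutes tolerated inside an open episode
MIN_RUN_MINUTES = 6  # "more than five consecutive minutes"


@dataclass(frozen=True)
class MateGuardEpisode:
    """A contiguous guarded interval of one female by one male."""

    male_id: str
    female_id: str
    date: dt.date
    start_minute: int  # minute of day of the first qualifying scan
    end_minute: int  # minute of day of the last qualifying scan

    @property
    def duration_min(self) -> int:
        return self.end_minute - self.start_minute + 1


@dataclass(frozen=True)
class MgDaySummary:
    male_id: str
    date: dt.date
    observed_min: int
    mg_min: int

    @property
    def mg_fraction(self) -> float:
        return self.mg_min / self.observed_min if self.observed_min else 0.0

    @property
    def extensive(self) -> bool:
        return self.mg_fraction > 0.5  # strict: exactly half is not extensive


@dataclass(frozen=True)
class MgPeriod:
    male_id: str
    female_ids: frozenset
    start_date: dt.date
    end_date: dt.date
    length_days: int  # observed extensive days in the run


def _minute_of_day(ts: pd.Series) -> pd.Series:
    ts = pd.to_datetime(ts)
    return ts.dt.hour * 60 + ts.dt.minute


def segment_episodes(scans: pd.DataFrame) -> list[MateGuardEpisode]:
    """Segment one male-day of minute scans into maximal MG episodes.

    ``scans`` must be a single male's scans for a single day, sorted by
    timestamp. Missing minutes (no scan row) count as non-qualifying
    grace minutes, exactly like minutes where the follow was lost.
    """
    if scans.empty:
        return []
    male_ids = scans["male_id"].unique()
    if len(male_ids) != 1:
        raise ValueError("segment_episodes expects a single male")
    ts = pd.to_datetime(scans["timestamp"])
    if len(ts.dt.date.unique()) != 1:
        raise ValueError("segment_episodes expects a single day (episodes never span midnight)")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("scans must be sorted with strictly increasing timestamps")

    male = male_ids[0]
    date = ts.dt.date.iloc[0]
    minutes = _minute_of_day(ts).to_numpy()
    females = scans["following_female"].to_numpy(dtype=object)
    close = scans["female_distance_le_10m"].to_numpy(dtype=object)

    # per-minute qualifying state over the observed span of the day
    state: dict[int, str | None] = {}
    for m, f, c in zip(minutes, females, close):
        qualifies = f is not None and not pd.isna(f) and c is not None and not pd.isna(c) and bool(c)
        state[int(m)] = str(f) if qualifies else None

    episodes: list[MateGuardEpisode] = []
    open_female: str | None = None
    open_start = 0
    last_qualify = 0
    grace = 0
    run_female: str | None = None
    run_start = 0
    run_len = 0

    def close_episode() -> None:
        nonlocal open_female
        episodes.append(
            MateGuardEpisode(str(male), open_female, date, open_start, last_qualify)
        )
        open_female = None

    for minute in range(minutes.min(), minutes.max() + 1):
        f = state.get(minute)
        if f is None:
            run_female, run_len = None, 0
            if open_female is not None:
                grace += 1
                if grace > GRACE_MINUTES:
                    close_episode()
            continue
        # minute qualifies for female f
        if f == run_female:
            run_len += 1
        else:
            run_female, run_start, run_len = f, minute, 1
        if open_female == f:
            last_qualify = minute
            grace = 0
        elif open_female is not None:
            # following a different female: grace for the open episode
            grace += 1
            if grace > GRACE_MINUTES:
                close_episode()
        if open_female is None and run_len >= MIN_RUN_MINUTES:
            open_female, open_start, last_qualify, grace = f, run_start, minute, 0
    if open_female is not None:
        close_episode()
    return episodes


def daily_mg_summary(
    episodes: list[MateGuardEpisode],
    scans: pd.DataFrame,
    count_out_of_sight: bool = False,
) -> MgDaySummary:
    """Summarise one male-day: observed minutes, MG minutes, extensive flag.

    ``observed_min`` counts minutes with a scan row; rows coded
    ``out_of_sight`` are excluded unless ``count_out_of_sight``. MG
    minutes count observed minutes falling inside an episode span, so the
    MG fraction is a true proportion of observation time.
    """
    ts = pd.to_datetime(scans["timestamp"])
    observed = scans if count_out_of_sight else scans[scans["activity"] != "out_of_sight"]
    obs_minutes = set(_minute_of_day(observed["timestamp"]).astype(int))
    mg_minutes: set[int] = set()
    for ep in episodes:
        mg_minutes |= set(range(ep.start_minute, ep.end_minute + 1)) & obs_minutes
    male = str(scans["male_id"].iloc[0])
    return MgDaySummary(male, ts.dt.date.iloc[0], len(obs_minutes), len(mg_minutes))


def mg_periods(day_summaries: list[MgDaySummary], episodes_by_day: dict | None = None) -> list[MgPeriod]:
    """Group a male's date-ordered day summaries into MG periods.

    A period is a maximal run of extensive days; unobserved calendar days
    in between do not break it, a non-extensive observed day does.
    ``episodes_by_day`` optionally maps date -> episode list so the
    period can record which females were guarded.
    """
    if not day_summaries:
        return []
    males = {s.male_id for s in day_summaries}
    if len(males) != 1:
        raise ValueError("mg_periods expects one male's summaries")
    ordered = sorted(day_summaries, key=lambda s: s.date)
    if len({s.date for s in ordered}) != len(ordered):
        raise ValueError("duplicate dates in day summaries")

    periods: list[MgPeriod] = []
    run: list[MgDaySummary] = []

    def flush() -> None:
        if not run:
            return
        females: set[str] = set()
        if episodes_by_day:
            for s in run:
                females |= {ep.female_id for ep in episodes_by_day.get(s.date, [])}
        periods.append(
            MgPeriod(run[0].male_id, frozenset(females), run[0].date, run[-1].date, len(run))
        )
        run.clear()

    for summary in ordered:
        if summary.extensive:
            run.append(summary)
        else:
            flush()
    flush()
    return periods


def mean_period_length(periods: list[MgPeriod]) -> float:
    """Mean MG period length in (observed) days."""
    if not periods:
        raise ValueError("no MG periods")
    return sum(p.length_days for p in periods) / len(periods)


def episodes_to_frame(episodes: list[MateGuardEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "male_id": e.male_id,
                "female_id": e.female_id,
                "date": e.date,
                "start_minute": e.start_minute,
                "end_minute": e.end_minute,
                "duration_min": e.duration_min,
            }
            for e in episodes
        ],
        columns=["male_id", "female_id", "date", "start_minute", "end_minute", "duration_min"],
    )


def summaries_to_frame(summaries: list[MgDaySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "male_id": s.male_id,
                "date": s.date,
                "observed_min": s.observed_min,
                "mg_min": s.mg_min,
                "mg_fraction": s.mg_fraction,
                "extensive": s.extensive,
            }
            for s in summaries
        ],
        columns=["male_id", "date", "observed_min", "mg_min", "mg_fraction", "extensive"],
    )
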
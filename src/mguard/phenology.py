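"""Monthly fruit-availability indices and their assignment to days.

Each territory's ~120 marked trees are scored monthly on an ordinal
log-abundance scale (0 = no fruit, 1 = 1-10 items, ... 5 = >10,000).
The working index is the percentage of trees fruiting (score >= 1),
which tracks the mean log score closely; surveys are dated to the last
day of their month and cover the window from the 16th of that month to
the 15th of the next.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd


class NoCoverage(LookupError):
    """The date falls outside every survey's assignment window."""


@dataclass(frozen=True)
class MonthlyFruitIndex:
    territory_id: str
    survey_date: dt.date  # month-end
    pct_trees_fruiting: float  # 0-100
    mean_log_score: float  # 0-5
    n_trees: int


def fruit_index(records: pd.DataFrame) -> MonthlyFruitIndex:
    """Index one territory-survey: % trees fruiting and mean log score."""
    territories = records["territory_id"].unique()
    dates = records["survey_date"].unique()
    if len(territories) != 1 or len(dates) != 1:
        raise ValueError("fruit_index expects one territory and one survey date")
    if records["tree_id"].duplicated().any():
        dup = records.loc[records["tree_id"].duplicated(), "tree_id"].iloc[0]
        raise ValueError(f"duplicate tree {dup!r} in survey")
    scores = records["fruit_score"]
    return MonthlyFruitIndex(
        territory_id=str(territories[0]),
        survey_date=pd.to_datetime(dates[0]).date(),
        pct_trees_fruiting=100.0 * (scores >= 1).mean(),
        mean_log_score=float(scores.mean()),
        n_trees=len(records),
    )


def monthly_indices(phenology: pd.DataFrame) -> pd.DataFrame:
    """All territory-survey indices from a long per-tree score table."""
    rows = [
        fruit_index(grp)
        for _, grp in phenology.groupby(["territory_id", "survey_date"], sort=True)
    ]
    return pd.DataFrame(
        [
            {
                "territory_id": r.territory_id,
                "survey_date": r.survey_date,
                "pct_trees_fruiting": r.pct_trees_fruiting,
                "mean_log_score": r.mean_log_score,
                "n_trees": r.n_trees,
            }
            for r in rows
        ]
    )


def _window_month(day: dt.date) -> tuple[int, int]:
    """Year/month of the survey covering ``day`` (16th of m .. 15th of m+1)."""
    if day.day >= 16:
        return day.year, day.month
    if day.month == 1:
        return day.year - 1, 12
    return day.year, day.month - 1


def assign_index(
    day: dt.date, indices: pd.DataFrame, territory_id: str, column: str = "pct_trees_fruiting"
) -> float:
    """Fruit availability for ``day``: the month-end survey whose window
    [16th of m, 15th of m+1] contains it."""
    year, month = _window_month(day)
    dates = pd.to_datetime(indices["survey_date"])
    hit = indices[
        (indices["territory_id"] == territory_id) & (dates.dt.year == year) & (dates.dt.month == month)
    ]
    if hit.empty:
        raise NoCoverage(f"no {territory_id} survey covering {day} (need month {year}-{month:02d})")
    return float(hit[column].iloc[0])
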
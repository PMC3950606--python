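"""Daily activity budgets, diet composition and restlessness.

All denominators are coded focal minutes (scan rows not marked
out-of-sight), following scan-sampling convention: the proportion of
time in a state is the proportion of 1-minute scans in that state.
Feeding takes precedence over the non-exclusive states (grooming,
self-grooming, travelling): a minute that is feeding-while-groomed
counts as feeding, because the analysis is about energetics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mguard.io import ACTIVITIES, FOOD_ITEMS, NON_EXCLUSIVE_STATES


class UndefinedDay(ValueError):
    """The day has too little coded data for the requested metric."""


MIN_FOCAL_MINUTES = 60  # male-days with less than 1 h of coded focal data are dropped


def _coded(scans: pd.DataFrame) -> pd.DataFrame:
    return scans[scans["activity"] != "out_of_sight"]


def resolved_activity(scans: pd.DataFrame) -> pd.Series:
    """Activity with feeding precedence applied (food item present => feeding)."""
    act = scans["activity"].copy()
    act[scans["food_item"].notna()] = "feeding"
    return act


def activity_budget(scans: pd.DataFrame, resolve_precedence: bool = True) -> pd.Series:
    """Per-activity proportions over coded minutes for one male-day.

    With ``resolve_precedence`` (the default, used by the models) any
    minute carrying a food item counts as feeding; the raw coded states
    are available with ``resolve_precedence=False``.
    """
    coded = _coded(scans)
    if coded.empty:
        raise UndefinedDay("no coded minutes")
    act = resolved_activity(coded) if resolve_precedence else coded["activity"]
    props = act.value_counts(normalize=True)
    return props.reindex([a for a in ACTIVITIES if a != "out_of_sight"], fill_value=0.0)


def diet_composition(scans: pd.DataFrame) -> pd.Series:
    """Proportions of each food item over feeding scans (sum to 1)."""
    feeding = scans[scans["food_item"].notna()]
    if feeding.empty:
        raise UndefinedDay("no feeding scans")
    return feeding["food_item"].value_counts(normalize=True).reindex(FOOD_ITEMS, fill_value=0.0)


def restlessness(scans: pd.DataFrame) -> float:
    """Rate of change in locomotion/position between consecutive coded minutes.

    For every coded minute whose predecessor minute (t-1) is also coded,
    emit 1 if locomotion/position differs from t-1, else 0; the score is
    the mean of the emitted values. Pairs spanning observation gaps are
    excluded, so the first minute of each contiguous block contributes no
    pair. Ranges over [0, 1]: 0 = never changes, 1 = changes every minute.
    """
    coded = _coded(scans).dropna(subset=["locomotion_position"])
    if len(coded) < 2:
        raise UndefinedDay("fewer than 2 coded minutes")
    ts = pd.to_datetime(coded["timestamp"])
    minutes = (ts.dt.hour * 60 + ts.dt.minute).to_numpy()
    loco = coded["locomotion_position"].to_numpy()
    consecutive = np.diff(minutes) == 1
    if not consecutive.any():
        raise UndefinedDay("no consecutive coded minute pairs")
    changes = loco[1:] != loco[:-1]
    return float(changes[consecutive].mean())


def daily_activity(scans: pd.DataFrame) -> dict:
    """All daily activity metrics for one male-day, as a flat record.

    Fruit share of diet and restlessness are NaN when undefined (no
    feeding scans / no consecutive pairs) rather than an error, so a
    month of days can be reduced with one call per day.
    """
    coded = _coded(scans)
    if coded.empty:
        raise UndefinedDay("no coded minutes")
    budget = activity_budget(scans)
    try:
        pct_fruit = float(diet_composition(scans)["fruit"])
    except UndefinedDay:
        pct_fruit = np.nan
    try:
        restless = restlessness(scans)
    except UndefinedDay:
        restless = np.nan
    ts = pd.to_datetime(scans["timestamp"])
    rec = {
        "male_id": str(scans["male_id"].iloc[0]),
        "date": ts.dt.date.iloc[0],
        "n_scans": int(len(coded)),
        "pct_fruit_in_diet": pct_fruit,
        "restlessness": restless,
    }
    rec.update({f"pct_{a}": float(budget[a]) for a in budget.index})
    return rec


def filter_days(daily: pd.DataFrame, min_minutes: int = MIN_FOCAL_MINUTES) -> pd.DataFrame:
    """Drop male-days with fewer than ``min_minutes`` coded focal minutes.

    Applied once, before any modelling: the day filter removes days too
    short to yield stable daily proportions.
    """
    return daily[daily["n_scans"] >= min_minutes].reset_index(drop=True)
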
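"""Assembly of the male-day model table and the per-sample UCP table.

One row per male-day: the daily responses (feeding %, fruit-in-diet %,
hourly travel, hourly vertical travel, restlessness), the MG percentage
of observation time, the fruit-availability index assigned to the day,
and daily rainfall. Days with less than one hour of coded focal data are
excluded before anything else. The UCP table has one row per retained
urine sample joined to the same-day behavioural metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mguard import activity as act
from mguard import guarding, movement, phenology


def daily_metrics(
    scans: pd.DataFrame,
    gps: pd.DataFrame | None = None,
    count_out_of_sight: bool = False,
) -> pd.DataFrame:
    """Reduce a full scan table (any males/days) to one row per male-day.

    Runs episode segmentation, the activity budget, restlessness and —
    when a GPS fix table with a ``male_id`` column is given — the
    movement metrics.
    """
    scans = scans.copy()
    scans["_date"] = pd.to_datetime(scans["timestamp"]).dt.date
    if gps is not None:
        gps = gps.copy()
        gps["_date"] = pd.to_datetime(gps["timestamp"]).dt.date
    rows = []
    for (male, date), day in scans.groupby(["male_id", "_date"], sort=True):
        day = day.sort_values("timestamp")
        episodes = guarding.segment_episodes(day)
        summary = guarding.daily_mg_summary(episodes, day, count_out_of_sight)
        try:
            rec = act.daily_activity(day)
        except act.UndefinedDay:
            continue
        rec["observed_min"] = summary.observed_min
        rec["mg_min"] = summary.mg_min
        rec["mg_pct"] = 100.0 * summary.mg_fraction
        rec["extensive_mg"] = summary.extensive
        if gps is not None:
            track = gps[(gps["male_id"] == male) & (gps["_date"] == date)]
            if len(track):
                mv = movement.daily_movement(track.drop(columns=["male_id", "_date"]), day)
                rec["hourly_distance_m"] = mv["hourly_distance_m"]
                rec["n_segments"] = mv["n_segments"]
            else:
                rec["hourly_distance_m"] = np.nan
                rec["n_segments"] = 0
            try:
                rec["hourly_vertical_m"] = movement.hourly_vertical(day)
            except act.UndefinedDay:
                rec["hourly_vertical_m"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def build_model_table(
    daily: pd.DataFrame,
    fruit_indices: pd.DataFrame,
    rainfall: pd.DataFrame,
    territory_of_male: dict,
    group_of_male: dict,
    min_minutes: int = act.MIN_FOCAL_MINUTES,
) -> pd.DataFrame:
    """Male-day model table: daily metrics + fruit index + rainfall.

    Applies the >= 1 h day filter; days outside phenology coverage get a
    missing fruit index (dropped later by the model). Predictors are
    left on their natural scales here — standardization happens inside
    :class:`mguard.inference.GuardingModel` so that every fitted table is
    standardized over exactly the rows entering that fit.
    """
    table = act.filter_days(daily, min_minutes).copy()
    rain = dict(zip(rainfall["date"], rainfall["rainfall_mm"]))
    fruit = []
    for _, row in table.iterrows():
        terr = territory_of_male[row["male_id"]]
        try:
            fruit.append(phenology.assign_index(row["date"], fruit_indices, terr))
        except phenology.NoCoverage:
            fruit.append(np.nan)
    table["fruit_index"] = fruit
    table["rainfall_mm"] = [rain.get(d, np.nan) for d in table["date"]]
    table["group_id"] = [group_of_male[m] for m in table["male_id"]]
    return table.reset_index(drop=True)


def build_ucp_table(
    measurements: pd.DataFrame,
    model_table: pd.DataFrame,
    rank_classes: dict,
    fruit_indices: pd.DataFrame | None = None,
    territory_of_male: dict | None = None,
    rainfall: pd.DataFrame | None = None,
    group_of_male: dict | None = None,
) -> pd.DataFrame:
    """One row per retained urine sample, joined to same-day behaviour.

    Samples from males or days without focal data keep missing
    behavioural columns (the MG model drops them; the rank model, which
    uses no behavioural covariates, retains them).
    """
    out = measurements.copy()
    ts = pd.to_datetime(out["collection_datetime"])
    out["date"] = ts.dt.date
    out["collection_time"] = ts.dt.hour + ts.dt.minute / 60.0
    key = model_table.set_index(["male_id", "date"])
    behav_cols = ["mg_pct", "pct_feeding", "hourly_vertical_m", "fruit_index", "rainfall_mm", "group_id"]
    joined = []
    for _, row in out.iterrows():
        k = (row["male_id"], row["date"])
        if k in key.index:
            joined.append(key.loc[k, behav_cols])
        else:
            joined.append(pd.Series({c: np.nan for c in behav_cols}))
    out = pd.concat([out.reset_index(drop=True), pd.DataFrame(joined).reset_index(drop=True)], axis=1)
    if fruit_indices is not None and territory_of_male is not None:
        # rank-model rows (control males) still need the environmental covariates
        missing = out["fruit_index"].isna()
        for i in out.index[missing]:
            terr = territory_of_male.get(out.at[i, "male_id"])
            if terr is None:
                continue
            try:
                out.at[i, "fruit_index"] = phenology.assign_index(out.at[i, "date"], fruit_indices, terr)
            except phenology.NoCoverage:
                pass
    if rainfall is not None:
        rain = dict(zip(rainfall["date"], rainfall["rainfall_mm"]))
        out["rainfall_mm"] = out["rainfall_mm"].fillna(out["date"].map(rain))
    if group_of_male is not None:
        out["group_id"] = out["group_id"].fillna(out["male_id"].map(group_of_male))
    out["rank_class"] = out["male_id"].map(rank_classes)
    return out
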
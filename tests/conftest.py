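import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mguard import io, simulate

BASE_DATE = dt.date(2021, 2, 1)


def make_scan_day(
    minutes,
    females=None,
    close=None,
    activities=None,
    locomotion=None,
    heights=None,
    food=None,
    male_id="M1",
    date=BASE_DATE,
    start_minute=480,
):
    """Build a one-male-day scan table from parallel per-minute lists.

    ``minutes`` are offsets from ``start_minute``; any per-minute list may
    be None (filled with a quiet default) or contain None/pd.NA entries.
    """
    n = len(minutes)
    females = females if females is not None else [None] * n
    close = close if close is not None else [None] * n
    activities = activities if activities is not None else ["resting"] * n
    locomotion = locomotion if locomotion is not None else ["sitting"] * n
    heights = heights if heights is not None else [2] * n
    food = food if food is not None else [None] * n
    base = dt.datetime.combine(date, dt.time(0)) + dt.timedelta(minutes=start_minute)
    rows = [
        {
            "male_id": male_id,
            "timestamp": base + dt.timedelta(minutes=int(m)),
            "activity": a,
            "locomotion_position": l,
            "height_category": h,
            "food_item": f,
            "following_female": fem,
            "female_distance_le_10m": c,
        }
        for m, a, l, h, f, fem, c in zip(minutes, activities, locomotion, heights, food, females, close)
    ]
    df = pd.DataFrame(rows, columns=io.SCAN_COLUMNS)
    df["height_category"] = df["height_category"].astype("Int64")
    df["female_distance_le_10m"] = df["female_distance_le_10m"].astype("boolean")
    return df


def random_scan_day(rng, n_minutes=None, male_id="M1"):
    """A random male-day exercising follows, distance flags and gaps."""
    n_minutes = n_minutes or int(rng.integers(30, 241))
    present = rng.random(n_minutes) > 0.08
    present[0] = True
    minutes = np.flatnonzero(present)
    n = len(minutes)
    female_choice = rng.choice([None, "F1", "F2"], size=n, p=[0.35, 0.45, 0.20])
    close = [
        (bool(rng.random() < 0.8) if f is not None and rng.random() > 0.1 else (None if f is None else pd.NA))
        for f in female_choice
    ]
    # distance flag only meaningful with a female; occasionally missing
    close = [c if f is not None else None for f, c in zip(female_choice, close)]
    activities = rng.choice(["resting", "travelling", "vigilant", "out_of_sight"], size=n, p=[0.4, 0.3, 0.2, 0.1])
    return make_scan_day(
        minutes,
        females=list(female_choice),
        close=close,
        activities=list(activities),
        male_id=male_id,
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by the slower integration tests."""
    return simulate.generate_study(simulate.StudyConfig(seed=11, n_days=60))


@pytest.fixture()
def rng():
    return np.random.default_rng(20210201)
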
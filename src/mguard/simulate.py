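"""Synthetic field study with known ground truth.

Emulates the structure of a two-mating-period field study on three
wild groups: per-male minute-resolution focal scans, minute GPS tracks
with isotropic positional error, monthly phenology surveys of 120 trees
per territory, daily rainfall, urine assays (weekly plus every other
day during mate-guarding periods) and a bared-teeth interaction matrix
consistent with a planted linear hierarchy.

Mate-guarding (MG) days arrive in consecutive blocks per male (a
two-state Markov chain over days) so that per-male overall MG time
spans roughly 8-54 % of observation time, and MG periods average a few
consecutive days. Daily behavioural responses are generated on the
standardized scale with additive AR(1) day-to-day residuals — exactly
the structure the inference stage assumes — and then realised as
minute-level multinomial draws, so segmentation, budgets and movement
metrics can be cross-checked against the generator's bookkeeping.

Two generators are provided: :func:`generate_study` emits the full raw
file bundle plus a :class:`GroundTruth`; :func:`generate_model_table`
directly emits the male-day model table at study scale for inference
calibration (the responses there carry the planted effects on the
standardized scale with no minute-level sampling noise).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mguard import io

DAY = dt.timedelta(days=1)


@dataclass
class StudyConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the footprint of the emulated study: 3 groups, 6
    focal (alpha/beta) males plus 2 low-ranking urine 'control' males
    per group, ~580 male-days passing the 1-h filter, and per-male MG
    time spanning roughly 8-54 % of observation time.
    """

    seed: int = 1
    n_groups: int = 3
    males_per_group: int = 2  # focal (alpha, beta)
    controls_per_group: int = 2  # urine-only low-ranking males
    n_days: int = 180
    start_date: dt.date = dt.date(2020, 12, 1)
    follow_schedule: str = "alternate"  # "daily" or "alternate"
    obs_minutes_range: tuple[int, int] = (90, 420)
    short_day_prob: float = 0.04  # occasional <1 h days, dropped by the filter
    # MG structure: per focal male target share of observation time spent MG
    mg_target_fracs: tuple[float, ...] = (0.27, 0.08, 0.40, 0.54, 0.37, 0.12)
    mg_day_guard_frac: tuple[float, float] = (0.55, 0.90)
    mg_period_continue_prob: float = 0.72  # mean period length ~ 1/(1-p) days
    episode_mean_min: float = 45.0
    # planted standardized effect sizes
    beta_mg_feeding: float = -2.0
    beta_mg_fruitdiet: float = -1.5
    beta_mg_vertical: float = -1.8
    beta_mg_distance: float = 0.0
    beta_mg_restless: float = 0.0
    beta_mg_ucp: float = 0.0  # null UCP effect: the study condition
    beta_fruit_feeding: float = -1.2
    beta_fruit_fruitdiet: float = 1.5
    residual_sd: float = 1.0
    ar1_rho: float = 0.4
    male_sd: float = 0.3
    group_sd: float = 0.2
    misspecified: bool = False  # heteroscedastic residuals for robustness checks
    # movement
    gps_error_m: float = 10.0
    speed_m_per_min: float = 2.3
    # phenology
    n_trees_per_territory: int = 120
    fruiting_base: float = 0.35
    fruiting_amplitude: float = 0.25
    fruiting_phase_days: float = 40.0
    # urine
    urine_weekly_every: int = 7
    ucp_log_median: float = np.log(3.0)
    ucp_log_sd: float = 0.35
    lyophilisation_lag_days: int = 90  # freeze-dry ~3 months after the study ends

    def validate(self) -> None:
        problems = []
        if self.residual_sd <= 0 or self.male_sd < 0 or self.group_sd < 0:
            problems.append("SDs must be positive")
        if not 0 <= self.ar1_rho < 1:
            problems.append("ar1_rho must be in [0, 1)")
        for p in (self.short_day_prob, self.mg_period_continue_prob, self.fruiting_base):
            if not 0 <= p <= 1:
                problems.append(f"probability {p} outside [0, 1]")
        if any(not 0 <= f <= 1 for f in self.mg_target_fracs):
            problems.append("mg_target_fracs must be proportions")
        if len(self.mg_target_fracs) != self.n_groups * self.males_per_group:
            problems.append("mg_target_fracs must have one entry per focal male")
        if self.follow_schedule not in ("daily", "alternate"):
            problems.append(f"unknown follow_schedule {self.follow_schedule!r}")
        if problems:
            raise ValueError("invalid study config: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Per-male-day generating quantities and the planted effect vector."""

    day_table: pd.DataFrame  # one row per generated male-day
    betas: dict
    hierarchy: dict  # group -> list of ids, alpha first
    ucp_truth: pd.DataFrame


@dataclass
class StudyData:
    """In-memory raw bundle; ``write`` emits the CSV dialects io reads."""

    scans: pd.DataFrame
    gps: pd.DataFrame
    phenology: pd.DataFrame
    rainfall: pd.DataFrame
    urine: pd.DataFrame
    interactions: dict  # group_id -> (ids, counts)
    territory_of_male: dict
    group_of_male: dict
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        io.write_scans(self.scans, outdir / "scans.csv")
        paths["scans"] = outdir / "scans.csv"
        gps = self.gps.copy()
        gps["timestamp"] = pd.to_datetime(gps["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        gps.to_csv(outdir / "gps.csv", index=False)
        paths["gps"] = outdir / "gps.csv"
        self.phenology.to_csv(outdir / "phenology.csv", index=False)
        self.rainfall.to_csv(outdir / "rainfall.csv", index=False)
        urine = self.urine.copy()
        urine["collection_datetime"] = pd.to_datetime(urine["collection_datetime"]).dt.strftime(
            "%Y-%m-%dT%H:%M"
        )
        urine.to_csv(outdir / "urine.csv", index=False)
        paths.update(
            phenology=outdir / "phenology.csv",
            rainfall=outdir / "rainfall.csv",
            urine=outdir / "urine.csv",
        )
        for gid, (ids, counts) in self.interactions.items():
            p = outdir / f"interactions_{gid}.csv"
            io.write_interaction_matrix(ids, counts, p)
            paths[f"interactions_{gid}"] = p
        meta = pd.DataFrame(
            [(m, self.group_of_male[m], self.territory_of_male[m]) for m in self.group_of_male],
            columns=["male_id", "group_id", "territory_id"],
        )
        meta.to_csv(outdir / "males.csv", index=False)
        paths["males"] = outdir / "males.csv"
        return paths


# ---------------------------------------------------------------------------
# helpers


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    eps = rng.normal(scale=sd, size=n)
    if n == 0:
        return eps
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1 - rho**2) if rho > 0 else eps[0]
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return x


def _mg_day_p(target_frac: float, schedule: str) -> float:
    """Calendar probability of an MG day so that the *observed* share of
    time spent guarding matches the per-male target.

    MG days are ~72 % guarded and carry ~1.9 % incidental guarding
    otherwise; under the alternate schedule every MG day is observed but
    only half the non-MG days, which oversamples MG relative to the
    calendar rate and must be corrected for.
    """
    g_mg, g_bg = 0.72, 0.019
    if schedule == "alternate":
        p = (target_frac / 2 - g_bg / 2) / max(1e-9, g_mg - g_bg / 2 - target_frac / 2)
    else:
        p = (target_frac - g_bg) / (g_mg - g_bg)
    return float(np.clip(p, 0.01, 0.95))


def _mg_day_sequence(rng: np.random.Generator, n_days: int, p_day: float, stay: float) -> np.ndarray:
    """Two-state day chain with stationary MG-day probability ``p_day``."""
    enter = p_day * (1 - stay) / max(1e-9, 1 - p_day)
    enter = min(enter, 0.95)
    state = np.zeros(n_days, dtype=bool)
    cur = rng.random() < p_day
    for d in range(n_days):
        state[d] = cur
        cur = (rng.random() < stay) if cur else (rng.random() < enter)
    return state


def _place_episodes(
    rng: np.random.Generator, obs_len: int, mg_minutes: int, mean_len: float
) -> list[tuple[int, int]]:
    """Split ``mg_minutes`` into episodes of >= 6 min placed inside the
    observation window with >= 3 min gaps between them, so segmentation
    recovers them exactly. Returns (start, end) offsets from window start."""
    mg_minutes = min(mg_minutes, obs_len)
    if mg_minutes < 6:
        return []
    lengths: list[int] = []
    remaining = mg_minutes
    while remaining >= 6:
        length = int(np.clip(rng.exponential(mean_len), 6, remaining))
        if remaining - length < 6:
            length = remaining
        lengths.append(length)
        remaining -= length
    # merge until the episodes plus their separating gaps fit the window
    while len(lengths) > 1 and sum(lengths) + 3 * (len(lengths) - 1) > obs_len:
        lengths[0] += lengths.pop()
    lengths[0] = min(lengths[0], obs_len)
    k = len(lengths)
    slack = obs_len - sum(lengths) - 3 * (k - 1)
    extra = np.sort(rng.integers(0, slack + 1, size=k)) if slack > 0 else np.zeros(k, dtype=int)
    extra_gaps = np.diff(np.concatenate([[0], extra]))
    out = []
    pos = int(extra_gaps[0]) if k > 0 else 0
    for i, length in enumerate(lengths):
        if i > 0:
            pos += 3 + int(extra_gaps[i])
        out.append((pos, pos + length - 1))
        pos += length
    return out


_LOCOMOTION = list(io.LOCOMOTION_POSITIONS)
_NONFEED_ACTIVITIES = ["resting", "vigilant", "travelling", "grooming", "affiliating", "aggressing"]
_NONFEED_P = np.array([0.42, 0.18, 0.22, 0.12, 0.04, 0.02])
_NONFRUIT_ITEMS = ["leaf", "flower", "arthropod", "other"]
_NONFRUIT_P = np.array([0.55, 0.25, 0.12, 0.08])


def generate_study(config: StudyConfig | None = None) -> StudyData:
    """Generate the complete raw study bundle plus ground truth.

    Deterministic under ``config.seed``: the same seed yields a
    byte-identical bundle.
    """
    cfg = config or StudyConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    groups = [f"G{g+1}" for g in range(cfg.n_groups)]
    territory_of_group = {g: f"T{g[1:]}" for g in groups}
    focal_males, group_of_male, territory_of_male = [], {}, {}
    control_males = []
    for g in groups:
        for k in range(cfg.males_per_group):
            m = f"{g}M{k+1}"
            focal_males.append(m)
            group_of_male[m] = g
            territory_of_male[m] = territory_of_group[g]
        for k in range(cfg.controls_per_group):
            m = f"{g}C{k+1}"
            control_males.append(m)
            group_of_male[m] = g
            territory_of_male[m] = territory_of_group[g]

    dates = [cfg.start_date + i * DAY for i in range(cfg.n_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates])

    # --- environment ---------------------------------------------------
    rain_amt = np.where(
        rng.random(cfg.n_days) < 0.55, rng.gamma(1.5, 8.0, cfg.n_days).round(1), 0.0
    )
    rainfall = pd.DataFrame({"date": dates, "rainfall_mm": rain_amt})

    month_ends = sorted(
        {
            (pd.Timestamp(d) + pd.offsets.MonthEnd(0)).date()
            for d in dates
        }
    )
    phen_rows = []
    for terr in sorted(set(territory_of_male.values())):
        toffset = rng.uniform(-15, 15)
        for me in month_ends:
            p = np.clip(
                cfg.fruiting_base
                + cfg.fruiting_amplitude
                * np.sin(2 * np.pi * (me.timetuple().tm_yday - cfg.fruiting_phase_days + toffset) / 365.0),
                0.02,
                0.95,
            )
            fruiting = rng.random(cfg.n_trees_per_territory) < p
            scores = np.where(fruiting, 1 + rng.binomial(4, 0.45, cfg.n_trees_per_territory), 0)
            phen_rows += [
                (terr, f"{terr}tree{t+1}", me, int(s)) for t, s in enumerate(scores)
            ]
    phenology = pd.DataFrame(phen_rows, columns=["territory_id", "tree_id", "survey_date", "fruit_score"])
    # day-level fruit index per territory (what the pipeline will recover)
    fruit_by_terr_month = (
        phenology.assign(score_ge1=lambda d: d["fruit_score"] >= 1)
        .groupby(["territory_id", "survey_date"])["score_ge1"]
        .mean()
        * 100.0
    )

    def day_fruit(terr: str, d: dt.date) -> float:
        if d.day >= 16:
            y, m = d.year, d.month
        elif d.month == 1:
            y, m = d.year - 1, 12
        else:
            y, m = d.year, d.month - 1
        me = (pd.Timestamp(y, m, 1) + pd.offsets.MonthEnd(0)).date()
        try:
            return float(fruit_by_terr_month.loc[(terr, me)])
        except KeyError:
            return float(fruit_by_terr_month.xs(terr, level=0).iloc[0])

    # --- per-male day plans --------------------------------------------
    betas = {
        "feeding": cfg.beta_mg_feeding,
        "fruit_diet": cfg.beta_mg_fruitdiet,
        "vertical": cfg.beta_mg_vertical,
        "distance": cfg.beta_mg_distance,
        "restlessness": cfg.beta_mg_restless,
        "ucp": cfg.beta_mg_ucp,
    }
    group_fx = {g: rng.normal(scale=cfg.group_sd) for g in groups}
    male_fx = {m: rng.normal(scale=cfg.male_sd) for m in focal_males + control_males}

    plans = []  # (male, date, obs_start, obs_len, mg_state, guard_frac)
    mg_state_by_male = {}
    for im, male in enumerate(focal_males):
        p_day = _mg_day_p(cfg.mg_target_fracs[im], cfg.follow_schedule)
        mg_days = _mg_day_sequence(rng, cfg.n_days, p_day, cfg.mg_period_continue_prob)
        mg_state_by_male[male] = mg_days
        offset = im % 2
        for d in range(cfg.n_days):
            if cfg.follow_schedule == "alternate" and not mg_days[d] and d % 2 != offset:
                continue
            if rng.random() < cfg.short_day_prob:
                obs_len = int(rng.integers(15, 59))
            else:
                obs_len = int(rng.integers(*cfg.obs_minutes_range))
            obs_start = int(rng.integers(360, 420))  # dawn start, 06:00-07:00
            guard = rng.uniform(*cfg.mg_day_guard_frac) if mg_days[d] else (
                rng.uniform(0.0, 0.25) if rng.random() < 0.15 else 0.0
            )
            plans.append((male, dates[d], obs_start, obs_len, bool(mg_days[d]), guard))

    # standardized MG fraction across planned days (population scaling)
    guard_fracs = np.array([p[5] for p in plans])
    mg_mu, mg_sd = guard_fracs.mean(), guard_fracs.std(ddof=1)

    # per-male AR(1) residual streams, one per response
    resp_names = ["feeding", "fruit_diet", "vertical", "distance", "restlessness"]
    ar_streams = {
        (m, r): _ar1(rng, cfg.n_days, cfg.ar1_rho, cfg.residual_sd)
        for m in focal_males
        for r in resp_names
    }

    fruit_all = np.array([day_fruit(territory_of_male[p[0]], p[1]) for p in plans])
    fruit_mu, fruit_sd = fruit_all.mean(), (fruit_all.std(ddof=1) or 1.0)

    scan_rows, gps_rows, truth_rows = [], [], []
    date_index = {d: i for i, d in enumerate(dates)}
    rain_by_date = dict(zip(dates, rain_amt))

    for (male, date, obs_start, obs_len, mg_day, guard_frac), fruit_val in zip(plans, fruit_all):
        di = date_index[date]
        z_mg = (guard_frac - mg_mu) / mg_sd
        z_fruit = (fruit_val - fruit_mu) / fruit_sd
        base_fx = group_fx[group_of_male[male]] + male_fx[male]

        def latent(resp: str, beta_fruit: float = 0.0) -> float:
            e = ar_streams[(male, resp)][di]
            if cfg.misspecified:
                e *= 1.0 + 0.5 * abs(z_mg)
            return betas[resp] * z_mg + beta_fruit * z_fruit + base_fx + e

        y_feed = latent("feeding", cfg.beta_fruit_feeding)
        y_fruitd = latent("fruit_diet", cfg.beta_fruit_fruitdiet)
        y_vert = latent("vertical")
        y_dist = latent("distance")
        y_rest = latent("restlessness")

        p_feed = float(np.clip(0.30 + 0.06 * y_feed, 0.03, 0.95))
        p_fruit = float(np.clip(0.55 + 0.08 * y_fruitd, 0.02, 0.98))
        p_step = float(np.clip(0.30 + 0.07 * y_vert, 0.02, 0.90))
        p_switch = float(np.clip(0.35 + 0.08 * y_rest, 0.05, 0.95))
        speed = float(np.clip(cfg.speed_m_per_min * np.exp(0.15 * y_dist), 0.3, 8.0))

        mg_min_target = int(round(guard_frac * obs_len))
        episodes = _place_episodes(rng, obs_len, mg_min_target, cfg.episode_mean_min) if mg_min_target >= 6 else []
        in_episode = np.zeros(obs_len, dtype=int)  # 0 = no, k = episode k
        for k, (a, b) in enumerate(episodes, start=1):
            in_episode[a : b + 1] = k
        female_of_episode = {k: f"F{male[-1]}{k}" for k in range(1, len(episodes) + 1)}

        # minute-level draws
        feeding = rng.random(obs_len) < p_feed
        fruit_item = rng.random(obs_len) < p_fruit
        nonfeed_idx = rng.choice(len(_NONFEED_ACTIVITIES), size=obs_len, p=_NONFEED_P)
        switch = rng.random(obs_len) < p_switch
        loco = np.empty(obs_len, dtype=object)
        loco[0] = _LOCOMOTION[rng.integers(len(_LOCOMOTION))]
        for t in range(1, obs_len):
            loco[t] = (
                _LOCOMOTION[rng.integers(len(_LOCOMOTION))] if switch[t] else loco[t - 1]
            )
        heights = np.empty(obs_len, dtype=int)
        heights[0] = int(rng.integers(1, 5))
        step = rng.random(obs_len) < p_step
        direction = rng.integers(0, 2, obs_len) * 2 - 1
        for t in range(1, obs_len):
            heights[t] = int(np.clip(heights[t - 1] + (direction[t] if step[t] else 0), 0, 6))

        # observation gaps / out-of-sight only outside episodes
        gap = (rng.random(obs_len) < 0.02) & (in_episode == 0)
        oos = (rng.random(obs_len) < 0.03) & (in_episode == 0) & ~gap
        if obs_len > 1:  # never lose the first minute: keeps day boundaries stable
            gap[0] = oos[0] = False

        day0 = dt.datetime.combine(date, dt.time(0)) + dt.timedelta(minutes=obs_start)
        for t in range(obs_len):
            if gap[t]:
                continue
            minute_ts = day0 + dt.timedelta(minutes=t)
            if oos[t]:
                scan_rows.append(
                    (male, minute_ts, "out_of_sight", None, None, None, None, None)
                )
                continue
            ep = in_episode[t]
            female = female_of_episode.get(ep)
            dist_flag = True if female else None
            if feeding[t]:
                activity_ = "feeding"
                item = "fruit" if fruit_item[t] else _NONFRUIT_ITEMS[rng.choice(len(_NONFRUIT_ITEMS), p=_NONFRUIT_P)]
            else:
                activity_ = _NONFEED_ACTIVITIES[nonfeed_idx[t]]
                item = None
            scan_rows.append(
                (male, minute_ts, activity_, loco[t], int(heights[t]), item, female, dist_flag)
            )

        # GPS: correlated-walk true path + isotropic error, minute fixes
        headings = np.cumsum(rng.normal(scale=0.5, size=obs_len))
        step_len = rng.exponential(speed, size=obs_len)
        dx = np.concatenate([[0], (step_len * np.cos(headings))[1:]])
        dy = np.concatenate([[0], (step_len * np.sin(headings))[1:]])
        true_x, true_y = np.cumsum(dx), np.cumsum(dy)
        err = rng.normal(scale=cfg.gps_error_m / np.sqrt(2), size=(obs_len, 2))
        coded = ~gap & ~oos
        for t in range(obs_len):
            gps_rows.append(
                (
                    male,
                    day0 + dt.timedelta(minutes=t),
                    true_x[t] + err[t, 0],
                    true_y[t] + err[t, 1],
                    bool(coded[t]),
                )
            )

        observed_min = int(coded.sum())
        mg_min = int(((in_episode > 0) & coded).sum())
        truth_rows.append(
            {
                "male_id": male,
                "date": date,
                "obs_len": obs_len,
                "observed_min": observed_min,
                "mg_day": mg_day,
                "true_mg_min": mg_min,
                "true_mg_frac": mg_min / observed_min if observed_min else 0.0,
                "n_episodes": len(episodes),
                "z_mg": z_mg,
                "fruit_index": fruit_val,
                "p_feed": p_feed,
                "p_fruit": p_fruit,
                "p_step": p_step,
                "p_switch": p_switch,
                "speed_m_per_min": speed,
                "true_path_m": float(step_len[1:].sum()),
                "y_feeding": y_feed,
                "y_fruit_diet": y_fruitd,
                "y_vertical": y_vert,
                "y_distance": y_dist,
                "y_restlessness": y_rest,
            }
        )

    scans = pd.DataFrame(scan_rows, columns=io.SCAN_COLUMNS)
    scans["timestamp"] = pd.to_datetime(scans["timestamp"])
    scans = scans.sort_values(["male_id", "timestamp"]).reset_index(drop=True)
    scans["height_category"] = scans["height_category"].astype("Int64")
    scans["female_distance_le_10m"] = scans["female_distance_le_10m"].astype("boolean")
    gps = pd.DataFrame(gps_rows, columns=["male_id", "timestamp", "x", "y", "has_focal_behaviour"])

    # --- urine ----------------------------------------------------------
    truth_df = pd.DataFrame(truth_rows)
    mg_frac_by_md = {(r["male_id"], r["date"]): r["true_mg_frac"] for r in truth_rows}
    urine_rows, ucp_truth_rows = [], []
    for male in focal_males + control_males:
        is_focal = male in focal_males
        mg_days = mg_state_by_male.get(male, np.zeros(cfg.n_days, dtype=bool))
        for d in range(cfg.n_days):
            date = dates[d]
            weekly = d % cfg.urine_weekly_every == (sum(map(ord, male)) % cfg.urine_weekly_every)
            alternate_mg = is_focal and mg_days[d] and d % 2 == 0
            if not (weekly or alternate_mg):
                continue
            if rng.random() < 0.25:  # missed collections
                continue
            t_coll = dt.datetime.combine(date, dt.time(6)) + dt.timedelta(
                minutes=int(rng.integers(0, 12 * 60))
            )
            mg_frac = mg_frac_by_md.get((male, date), 0.0)
            z_mg = (mg_frac - mg_mu) / mg_sd
            log_ucp = (
                cfg.ucp_log_median
                + 0.25 * cfg.beta_mg_ucp * z_mg
                + 0.5 * male_fx[male]
                + rng.normal(scale=cfg.ucp_log_sd)
            )
            creat = float(np.round(np.exp(rng.normal(np.log(0.8), 0.5)), 3))
            cpep = float(np.round(np.exp(log_ucp) * creat, 3))
            storage = float(
                np.round((cfg.n_days - d + cfg.lyophilisation_lag_days) / 30.44, 2)
            )
            orig_vol = float(np.round(rng.uniform(0.2, 1.8), 1))
            recon_vol = 0.3 if orig_vol < 0.5 else 0.5
            urine_rows.append(
                (male, t_coll, cpep, creat, storage, orig_vol, recon_vol)
            )
            ucp_truth_rows.append(
                {
                    "male_id": male,
                    "collection_datetime": t_coll,
                    "true_log_ucp": log_ucp,
                    "mg_frac": mg_frac,
                    "storage_months": storage,
                }
            )
    urine = pd.DataFrame(urine_rows, columns=io.URINE_COLUMNS)

    # --- interaction matrices (planted hierarchy) -----------------------
    interactions, hierarchy = {}, {}
    for g in groups:
        ids = [m for m in focal_males + control_males if group_of_male[m] == g]
        hierarchy[g] = ids  # alpha first: G?M1, G?M2, then controls
        n = len(ids)
        counts = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if i > j:  # lower-ranked i signals submission up the order
                    counts[i, j] = rng.poisson(5) + 1
                elif rng.random() < 0.08:  # rare reversed displays
                    counts[i, j] = rng.poisson(1)
        interactions[g] = (ids, counts)

    truth = GroundTruth(
        day_table=truth_df,
        betas={**betas, "fruit_feeding": cfg.beta_fruit_feeding, "fruit_fruitdiet": cfg.beta_fruit_fruitdiet},
        hierarchy=hierarchy,
        ucp_truth=pd.DataFrame(ucp_truth_rows),
    )
    return StudyData(
        scans=scans,
        gps=gps,
        phenology=phenology,
        rainfall=rainfall,
        urine=urine,
        interactions=interactions,
        territory_of_male=territory_of_male,
        group_of_male=group_of_male,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# table-level generator for inference calibration


def generate_model_table(
    n_rows: int = 580,
    n_males: int = 6,
    n_groups: int = 3,
    beta_mg: float = 0.0,
    beta_fruit: float = 0.0,
    beta_rain: float = 0.0,
    rho: float = 0.4,
    residual_sd: float = 1.0,
    male_sd: float = 0.3,
    group_sd: float = 0.2,
    response: str = "pct_feeding",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Male-day model table simulated directly at the daily level.

    Predictors are sample-standardized before the response is built, so
    the planted coefficients are exactly on the fitted (standardized)
    scale; residuals are AR(1) within male over consecutive days.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    males = [f"M{i+1}" for i in range(n_males)]
    group_of = {m: f"G{i % n_groups + 1}" for i, m in enumerate(males)}
    per_male = int(np.ceil(n_rows / n_males))
    rows = []
    start = dt.date(2021, 1, 1)
    for m in males:
        n_m = min(per_male, n_rows - len(rows))
        resid = _ar1(rng, n_m, rho, residual_sd)
        mg = np.clip(rng.beta(0.4, 1.2, n_m), 0, 1) * 100
        fruit = rng.uniform(5, 60, n_m)
        rain = np.where(rng.random(n_m) < 0.55, rng.gamma(1.5, 8.0, n_m), 0.0)
        for k in range(n_m):
            rows.append(
                {
                    "male_id": m,
                    "group_id": group_of[m],
                    "date": start + k * DAY,
                    "mg_pct": mg[k],
                    "fruit_index": fruit[k],
                    "rainfall_mm": rain[k],
                    "_resid": resid[k],
                }
            )
        if len(rows) >= n_rows:
            break
    df = pd.DataFrame(rows)
    from mguard.inference import standardize  # local import avoids cycle

    z_mg = standardize(df["mg_pct"])
    z_fruit = standardize(df["fruit_index"])
    z_rain = standardize(df["rainfall_mm"])
    g_fx = {g: rng.normal(scale=group_sd) for g in set(group_of.values())}
    m_fx = {m: rng.normal(scale=male_sd) for m in males}
    df[response] = (
        beta_mg * z_mg
        + beta_fruit * z_fruit
        + beta_rain * z_rain
        + df["group_id"].map(g_fx).to_numpy()
        + df["male_id"].map(m_fx).to_numpy()
        + df["_resid"].to_numpy()
    )
    return df.drop(columns="_resid")


# ---------------------------------------------------------------------------
# hand-auditable worked days


def emit_worked_day(scenario: str, male_id: str = "M1", date: dt.date = dt.date(2021, 2, 1)) -> pd.DataFrame:
    """Tiny fixture days encoding the segmentation edge cases.

    Scenarios: ``boundary_5min`` (exactly 5 qualifying minutes — no
    episode), ``grace_window`` (8 + 2 far + 8 — one 18-min episode),
    ``female_switch`` (10 min on F1 then 10 on F2 — two episodes),
    ``gap`` (8 qualifying, 3 unobserved, 8 qualifying — two episodes).
    """
    base = dt.datetime.combine(date, dt.time(8, 0))

    def row(t: int, female=None, close=None, activity="travelling"):
        return {
            "male_id": male_id,
            "timestamp": base + dt.timedelta(minutes=t),
            "activity": activity,
            "locomotion_position": "walking",
            "height_category": 2,
            "food_item": None,
            "following_female": female,
            "female_distance_le_10m": close,
        }

    rows = []
    if scenario == "boundary_5min":
        rows += [row(t, "F1", True) for t in range(5)]
        rows += [row(t, activity="resting") for t in range(5, 30)]
    elif scenario == "grace_window":
        rows += [row(t, "F1", True) for t in range(8)]
        rows += [row(t, "F1", False) for t in range(8, 10)]  # > 10 m, grace
        rows += [row(t, "F1", True) for t in range(10, 18)]
        rows += [row(t, activity="resting") for t in range(18, 40)]
    elif scenario == "female_switch":
        rows += [row(t, "F1", True) for t in range(10)]
        rows += [row(t, "F2", True) for t in range(10, 20)]
        rows += [row(t, activity="resting") for t in range(20, 40)]
    elif scenario == "gap":
        rows += [row(t, "F1", True) for t in range(8)]
        rows += [row(t, "F1", True) for t in range(11, 19)]  # minutes 8-10 unobserved
        rows += [row(t, activity="resting") for t in range(19, 40)]
    else:
        raise ValueError(f"unknown worked-day scenario {scenario!r}")
    df = pd.DataFrame(rows, columns=io.SCAN_COLUMNS)
    df["height_category"] = df["height_category"].astype("Int64")
    df["female_distance_le_10m"] = df["female_distance_le_10m"].astype("boolean")
    return df
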
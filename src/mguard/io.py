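"""Readers and writers for the tabular field-data formats.

All tables travel as RFC-4180 CSV with fixed, documented column dialects
(one row per minute-scan; ISO-8601 timestamps; lower-case enum tokens).
GPS tracks are accepted as GPX 1.1 or CSV; lon/lat coordinates are
converted on load to a local transverse-Mercator metric frame so that all
downstream distances are planar Euclidean (home ranges are tens of
hectares, so planar error is negligible against the ±10 m GPS noise).

Loading never silently drops rows: with ``on_invalid="collect"`` the
reader returns the valid records together with a reject table carrying
the 1-based line number and reason for every row refused.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_008.8

ACTIVITIES = (
    "resting",
    "vigilant",
    "feeding",
    "drinking",
    "travelling",
    "aggressing",
    "affiliating",
    "grooming",
    "self_grooming",
    "out_of_sight",
)
#: activities that are mutually exclusive once feeding precedence is applied
LOCOMOTION_POSITIONS = ("lying", "sitting", "standing", "walking", "running", "jumping", "climbing")
FOOD_ITEMS = ("fruit", "leaf", "flower", "arthropod", "bark", "mushroom", "other")
#: states that may co-occur with feeding in the field protocol
NON_EXCLUSIVE_STATES = ("grooming", "self_grooming", "travelling")

SCAN_COLUMNS = [
    "male_id",
    "timestamp",
    "activity",
    "locomotion_position",
    "height_category",
    "food_item",
    "following_female",
    "female_distance_le_10m",
]

GPS_CSV_COLUMNS_XY = ["timestamp", "x", "y"]
GPS_CSV_COLUMNS_LONLAT = ["timestamp", "lon", "lat"]


class FormatError(ValueError):
    """The file does not match the documented dialect (wrong columns, bad values)."""


class ValidationError(ValueError):
    """Rows parse but violate a domain invariant."""


@dataclass
class LoadReport:
    """Valid records plus an accounting of every rejected row."""

    records: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["line", "reason"]))

    @property
    def n_in(self) -> int:
        return len(self.records) + len(self.rejects)


# ---------------------------------------------------------------------------
# scans


def _check_scan_columns(df: pd.DataFrame) -> None:
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"scan file is missing required columns: {missing}")


def _scan_row_problem(row: pd.Series) -> str | None:
    """Return a reason string if the row violates a ScanRecord invariant."""
    if row["activity"] not in ACTIVITIES:
        return f"unknown activity {row['activity']!r}"
    loc = row["locomotion_position"]
    if pd.notna(loc) and loc not in LOCOMOTION_POSITIONS:
        return f"unknown locomotion/position {loc!r}"
    h = row["height_category"]
    if pd.notna(h) and not (0 <= int(h) <= 6):
        return f"height category {h} outside 0-6"
    item = row["food_item"]
    if pd.notna(item):
        if item not in FOOD_ITEMS:
            return f"unknown food item {item!r}"
        if row["activity"] != "feeding":
            return f"food item recorded but activity is {row['activity']!r}"
    if pd.notna(row["female_distance_le_10m"]) and pd.isna(row["following_female"]):
        return "distance flag present without a followed female"
    return None


def read_scans(
    path: str | Path,
    on_invalid: str = "raise",
    resolve_feeding_precedence: bool = False,
) -> pd.DataFrame | LoadReport:
    """Read a minute-scan CSV into a validated scan table.

    Parameters
    ----------
    path
        CSV with the columns in :data:`SCAN_COLUMNS`.
    on_invalid
        ``"raise"`` (default) raises :class:`ValidationError` naming the
        offending 1-based line numbers; ``"collect"`` returns a
        :class:`LoadReport` with the valid rows and a reject table.
    resolve_feeding_precedence
        If true, a row with a food item but a non-exclusive activity
        (grooming, self-grooming, travelling) is coerced to
        ``activity="feeding"`` instead of rejected, mirroring the field
        precedence rule; a food item on an exclusive non-feeding state is
        still invalid.
    """
    if on_invalid not in ("raise", "collect"):
        raise ValueError("on_invalid must be 'raise' or 'collect'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"male_id": str, "following_female": str})
    _check_scan_columns(df)
    df = df[SCAN_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["height_category"] = df["height_category"].astype("Int64")
    df["female_distance_le_10m"] = df["female_distance_le_10m"].map(
        {True: True, False: False, "true": True, "false": False, 1: True, 0: False}
    ).astype("boolean")

    if resolve_feeding_precedence:
        coerce = df["food_item"].notna() & df["activity"].isin(NON_EXCLUSIVE_STATES)
        df.loc[coerce, "activity"] = "feeding"

    problems = []
    for i, row in df.iterrows():
        reason = _scan_row_problem(row)
        if reason is not None:
            problems.append((i + 2, reason))  # +2: header line + 1-based

    bad_idx = [line - 2 for line, _ in problems]
    good = df.drop(index=bad_idx)

    # monotonicity within a male-day is structural, not row-local: always an error
    for (male, day), grp in good.groupby([good["male_id"], good["timestamp"].dt.date]):
        ts = grp["timestamp"].values
        if len(ts) > 1 and not (np.diff(ts) > np.timedelta64(0, "s")).all():
            raise ValidationError(
                f"timestamps not strictly increasing for male {male} on {day}"
            )

    if problems and on_invalid == "raise":
        msg = "; ".join(f"line {line}: {reason}" for line, reason in problems[:10])
        raise ValidationError(f"{len(problems)} invalid scan rows ({msg})")
    report = LoadReport(
        records=good.reset_index(drop=True),
        rejects=pd.DataFrame(problems, columns=["line", "reason"]),
    )
    if on_invalid == "collect":
        return report
    return report.records


def write_scans(df: pd.DataFrame, path: str | Path) -> None:
    """Write a scan table in the canonical dialect (lossless round trip)."""
    out = df[SCAN_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GPS


def transverse_mercator(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to metres on a spherical transverse Mercator
    centred at (lon0, lat0). Exact closed form; adequate wherever the study
    area is small compared with the Earth's radius."""
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = math.radians(lat0)
    b = np.cos(phi) * np.sin(lam)
    x = EARTH_RADIUS_M * np.arctanh(b)
    y = EARTH_RADIUS_M * (np.arctan2(np.tan(phi), np.cos(lam)) - phi0)
    return x, y


def _parse_gpx(path: Path) -> pd.DataFrame:
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    rows = []
    pts = root.findall(".//gpx:trkpt", ns)
    if not pts:  # tolerate un-namespaced files
        pts = root.findall(".//trkpt")
    for pt in pts:
        t = pt.find("gpx:time", ns)
        if t is None:
            t = pt.find("time")
        if t is None or pt.get("lat") is None or pt.get("lon") is None:
            raise FormatError("GPX track point missing lat/lon/time")
        rows.append((t.text, float(pt.get("lon")), float(pt.get("lat"))))
    return pd.DataFrame(rows, columns=["timestamp", "lon", "lat"])


def read_gps(
    path: str | Path,
    origin: tuple[float, float] | None = None,
    focal_minutes: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Read a GPS track (GPX 1.1 or CSV) into a metric planar fix table.

    Returns a DataFrame with ``timestamp, x, y, has_focal_behaviour``.
    CSV input may carry either projected ``x, y`` (metres, used verbatim)
    or ``lon, lat`` (degrees, projected on load). ``origin`` fixes the
    projection centre (lon0, lat0); by default the track's mean position
    is used. ``focal_minutes`` optionally supplies the timestamps at which
    focal behaviour was coded; fixes outside it get
    ``has_focal_behaviour=False``. A ``has_focal_behaviour`` CSV column,
    when present, is honoured instead.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        df = _parse_gpx(path)
    else:
        df = pd.read_csv(path)
        if not (
            set(GPS_CSV_COLUMNS_XY) <= set(df.columns)
            or set(GPS_CSV_COLUMNS_LONLAT) <= set(df.columns)
        ):
            raise FormatError(
                "GPS CSV needs columns timestamp,x,y (metres) or timestamp,lon,lat (degrees)"
            )
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601", utc=True).dt.tz_localize(None)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable GPS timestamp: {exc}") from exc

    if "x" not in df.columns:
        try:
            lonlat = df[["lon", "lat"]].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparseable lon/lat in GPS input: {exc}") from exc
        if not np.isfinite(lonlat).all():
            raise FormatError("non-finite lon/lat in GPS input")
        lon0, lat0 = origin if origin is not None else (df["lon"].mean(), df["lat"].mean())
        df["x"], df["y"] = transverse_mercator(df["lon"].to_numpy(), df["lat"].to_numpy(), lon0, lat0)
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise FormatError("non-finite coordinates in GPS input")
    if "has_focal_behaviour" not in df.columns:
        if focal_minutes is not None:
            focal = pd.to_datetime(pd.Series(focal_minutes)).dt.floor("min")
            df["has_focal_behaviour"] = df["timestamp"].dt.floor("min").isin(set(focal))
        else:
            df["has_focal_behaviour"] = True
    df["has_focal_behaviour"] = df["has_focal_behaviour"].astype(bool)

    df = df.sort_values("timestamp").reset_index(drop=True)
    ts = df["timestamp"].values
    if len(ts) > 1 and not (np.diff(ts) > np.timedelta64(0, "s")).all():
        raise ValidationError("duplicate or non-increasing GPS timestamps")
    return df[["timestamp", "x", "y", "has_focal_behaviour"]]


def write_gps_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_gpx(df: pd.DataFrame, path: str | Path, origin: tuple[float, float]) -> None:
    """Write fixes as GPX 1.1, inverting the local projection to lon/lat."""
    lon0, lat0 = origin
    phi0 = math.radians(lat0)
    x = df["x"].to_numpy() / EARTH_RADIUS_M
    y = df["y"].to_numpy() / EARTH_RADIUS_M + phi0
    # inverse spherical transverse Mercator
    lam = np.arctan2(np.sinh(x), np.cos(y))
    phi = np.arcsin(np.sin(y) / np.cosh(x))
    lon = np.degrees(lam) + lon0
    lat = np.degrees(phi)
    root = ET.Element("gpx", version="1.1", creator="mguard", xmlns="http://www.topografix.com/GPX/1/1")
    seg = ET.SubElement(ET.SubElement(root, "trk"), "trkseg")
    for t, lo, la in zip(pd.to_datetime(df["timestamp"]), lon, lat):
        pt = ET.SubElement(seg, "trkpt", lat=f"{la:.8f}", lon=f"{lo:.8f}")
        ET.SubElement(pt, "time").text = t.strftime("%Y-%m-%dT%H:%M:%SZ")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# phenology / rainfall / urine / interactions


def read_phenology(path: str | Path) -> pd.DataFrame:
    """Monthly per-tree fruit scores: territory_id, tree_id, survey_date, fruit_score (0-5)."""
    df = pd.read_csv(path, dtype={"territory_id": str, "tree_id": str})
    required = {"territory_id", "tree_id", "survey_date", "fruit_score"}
    if not required <= set(df.columns):
        raise FormatError(f"phenology file needs columns {sorted(required)}")
    df["survey_date"] = pd.to_datetime(df["survey_date"]).dt.date
    if not df["fruit_score"].isin(range(6)).all():
        bad = df.loc[~df["fruit_score"].isin(range(6))].index[0] + 2
        raise ValidationError(f"fruit score outside 0-5 at line {bad}")
    dup = df.duplicated(["territory_id", "tree_id", "survey_date"])
    if dup.any():
        raise ValidationError(
            f"duplicate tree record at line {df.index[dup][0] + 2}"
        )
    return df


def read_rainfall(path: str | Path) -> pd.DataFrame:
    """Daily rainfall: date, rainfall_mm."""
    df = pd.read_csv(path)
    if not {"date", "rainfall_mm"} <= set(df.columns):
        raise FormatError("rainfall file needs columns date, rainfall_mm")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["rainfall_mm"] < 0).any():
        raise ValidationError("negative rainfall")
    return df


URINE_COLUMNS = [
    "male_id",
    "collection_datetime",
    "cpeptide_ng_per_ml",
    "creatinine_mg_per_ml",
    "storage_months_before_lyophilisation",
    "original_volume_ml",
    "reconstitution_volume_ml",
]


def read_urine(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"male_id": str})
    missing = [c for c in URINE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"urine file is missing columns: {missing}")
    df["collection_datetime"] = pd.to_datetime(df["collection_datetime"])
    for col in ("cpeptide_ng_per_ml", "creatinine_mg_per_ml", "storage_months_before_lyophilisation"):
        if (df[col] < 0).any() or not np.isfinite(df[col]).all():
            raise ValidationError(f"negative or non-finite {col}")
    return df[URINE_COLUMNS]


def read_interaction_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Directed bared-teeth counts. CSV: first column = giver id, remaining
    columns = receiver ids; counts[i][j] = displays given by i to j."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise FormatError("interaction matrix rows and columns must list the same individuals in order")
    counts = df.to_numpy()
    if counts.shape[0] != counts.shape[1]:
        raise FormatError("interaction matrix must be square")
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.number):
        raise ValidationError("interaction counts must be non-negative")
    if np.diag(counts).any():
        raise ValidationError("interaction matrix diagonal must be zero")
    return ids, counts.astype(int)


def write_interaction_matrix(ids: list[str], counts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(counts, index=ids, columns=ids).to_csv(path)
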
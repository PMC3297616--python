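"""Reading, validating and writing the four CSV schemas, plus great-circle distance.

All tables are carried as pandas DataFrames with a documented, validated
schema.  Dates are ISO-8601 and interpreted in a single (logger-local) clock;
a calendar "day" is a date in that clock.  Validation never silently coerces:
every rejected row is reported with its row number and offending column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

HABITATS = ("ocean_reef", "deep_lagoon", "shallow_lagoon")
TAG_BATTERY_DAYS = {"V9": 365, "V16": 540}

TAG_COLUMNS = [
    "shark_id", "transmitter_id", "tag_type", "battery_days", "attachment",
    "tag_date", "sex", "total_length_cm", "maturity", "tagging_site_label",
    "tag_lat", "tag_lon",
]
RECEIVER_COLUMNS = ["receiver_id", "lat", "lon", "habitat", "depth_m", "op_start", "op_end"]
DETECTION_COLUMNS = ["timestamp", "receiver_id", "transmitter_id"]
BRUV_COLUMNS = [
    "site", "reserve", "date", "lat", "lon", "depth_m", "flow_velocity",
    "temp_start", "temp_end", "salinity", "ph", "dissolved_oxygen",
    "visibility_m", "presence", "nmax", "nmax_a",
]


class SchemaError(ValueError):
    """A required column is missing or the file cannot be parsed at all."""


class ValidationError(ValueError):
    """One or more rows violate an invariant; carries per-row reports."""

    def __init__(self, reports: list[tuple[int, str, str]]):
        self.reports = reports
        lines = "; ".join(f"row {r}: column {c}: {m}" for r, c, m in reports)
        super().__init__(f"{len(reports)} invalid row(s): {lines}")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _parse_dates(df, col, reports, fmt_kind="date"):
    parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    for i in df.index[parsed.isna() & df[col].notna()]:
        reports.append((int(i), col, f"unparseable {fmt_kind}: {df.loc[i, col]!r}"))
    return parsed


def read_tags(path) -> pd.DataFrame:
    """Read a tag-deployment table (one row per tagged shark).

    Enforces: tag_type in {V9, V16} with the matching battery life
    (365 / 540 days), positive total length, coordinates on the globe.
    Extra columns (e.g. packaged monitoring metrics) pass through untouched.
    """
    df = pd.read_csv(path)
    _require_columns(df, TAG_COLUMNS, "tags")
    if df.empty:
        return df
    reports: list[tuple[int, str, str]] = []
    df = df.copy()
    df["tag_date"] = _parse_dates(df, "tag_date", reports)
    for i, row in df.iterrows():
        if row["tag_type"] not in TAG_BATTERY_DAYS:
            reports.append((int(i), "tag_type", f"unknown tag type {row['tag_type']!r}"))
        elif int(row["battery_days"]) != TAG_BATTERY_DAYS[row["tag_type"]]:
            reports.append((int(i), "battery_days",
                            f"{row['battery_days']} inconsistent with {row['tag_type']} "
                            f"(expected {TAG_BATTERY_DAYS[row['tag_type']]})"))
        if row["attachment"] not in ("internal", "external"):
            reports.append((int(i), "attachment", f"unknown attachment {row['attachment']!r}"))
        if row["sex"] not in ("F", "M"):
            reports.append((int(i), "sex", f"unknown sex {row['sex']!r}"))
        if row["maturity"] not in ("adult", "juvenile"):
            reports.append((int(i), "maturity", f"unknown maturity {row['maturity']!r}"))
        if not row["total_length_cm"] > 0:
            reports.append((int(i), "total_length_cm", "must be positive"))
        if not (abs(row["tag_lat"]) <= 90 and abs(row["tag_lon"]) <= 180):
            reports.append((int(i), "tag_lat", "coordinates off the globe"))
    if reports:
        raise ValidationError(reports)
    df["shark_id"] = df["shark_id"].astype(str)
    df["transmitter_id"] = df["transmitter_id"].astype(str)
    return df


def read_receivers(path) -> pd.DataFrame:
    """Read a receiver-station table; repeated rows per operational interval.

    Returns one row per (receiver, interval) with parsed op_start/op_end.
    Intervals for one receiver must be pairwise non-overlapping (gaps between
    them express refurbishment downtime).
    """
    df = pd.read_csv(path)
    _require_columns(df, RECEIVER_COLUMNS, "receivers")
    if df.empty:
        return df
    reports: list[tuple[int, str, str]] = []
    df = df.copy()
    df["op_start"] = _parse_dates(df, "op_start", reports)
    df["op_end"] = _parse_dates(df, "op_end", reports)
    for i, row in df.iterrows():
        if row["habitat"] not in HABITATS:
            reports.append((int(i), "habitat", f"unknown habitat {row['habitat']!r}"))
        if not (abs(row["lat"]) <= 90 and abs(row["lon"]) <= 180):
            reports.append((int(i), "lat", "coordinates off the globe"))
        if pd.notna(row["op_start"]) and pd.notna(row["op_end"]) and row["op_start"] > row["op_end"]:
            reports.append((int(i), "op_start", "interval start after end"))
    if not reports:
        for rid, grp in df.groupby("receiver_id"):
            grp = grp.sort_values("op_start")
            prev_end = None
            for i, row in grp.iterrows():
                if prev_end is not None and row["op_start"] <= prev_end:
                    reports.append((int(i), "op_start",
                                    f"receiver {rid}: overlapping operational intervals"))
                prev_end = row["op_end"]
    if reports:
        raise ValidationError(reports)
    df["receiver_id"] = df["receiver_id"].astype(str)
    return df


@dataclass
class DetectionLog:
    """A QC'd raw detection log.

    detections: clean rows (timestamp, receiver_id, transmitter_id), sorted.
    quarantined: rows whose ids did not resolve against the tag/receiver
        tables (kept for audit, never silently dropped).
    n_duplicates: count of exact duplicate triples collapsed on read.
    """

    detections: pd.DataFrame
    quarantined: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_duplicates: int = 0


def read_detections(path, tags: pd.DataFrame | None = None,
                    receivers: pd.DataFrame | None = None) -> DetectionLog:
    """Read a VR2-export-like detection log.

    Exact duplicate (timestamp, receiver, transmitter) triples are collapsed
    and counted; rows referencing unknown transmitters or receivers are
    quarantined with a warning when reference tables are supplied.
    """
    df = pd.read_csv(path)
    _require_columns(df, DETECTION_COLUMNS, "detections")
    reports: list[tuple[int, str, str]] = []
    df = df.copy()
    df["timestamp"] = _parse_dates(df, "timestamp", reports, "timestamp")
    if reports:
        raise ValidationError(reports)
    df["receiver_id"] = df["receiver_id"].astype(str)
    df["transmitter_id"] = df["transmitter_id"].astype(str)
    n_before = len(df)
    df = df.drop_duplicates(subset=DETECTION_COLUMNS)
    n_dup = n_before - len(df)
    if n_dup:
        logger.info("collapsed %d duplicate detection(s)", n_dup)
    bad = pd.Series(False, index=df.index)
    if tags is not None:
        bad |= ~df["transmitter_id"].isin(set(tags["transmitter_id"].astype(str)))
    if receivers is not None:
        bad |= ~df["receiver_id"].isin(set(receivers["receiver_id"].astype(str)))
    quarantined = df[bad]
    if len(quarantined):
        logger.warning("quarantined %d detection(s) with unresolvable ids", len(quarantined))
    clean = df[~bad].sort_values(["transmitter_id", "receiver_id", "timestamp"]).reset_index(drop=True)
    return DetectionLog(clean, quarantined.reset_index(drop=True), n_dup)


def read_bruv(path) -> pd.DataFrame:
    """Read a BRUV deployment table.

    presence must equal 1 iff nmax >= 1, and nmax_a >= nmax (distinguishing
    individuals across the video can only reveal more sharks than one frame).
    Missing environmental fields are permitted and flagged in a boolean
    ``env_complete`` column rather than dropped.
    """
    df = pd.read_csv(path)
    _require_columns(df, BRUV_COLUMNS, "bruv")
    if df.empty:
        df["env_complete"] = pd.Series(dtype=bool)
        return df
    reports: list[tuple[int, str, str]] = []
    df = df.copy()
    df["date"] = _parse_dates(df, "date", reports)
    for i, row in df.iterrows():
        if int(row["presence"]) != int(int(row["nmax"]) >= 1):
            reports.append((int(i), "presence", "presence must be 1 iff nmax >= 1"))
        if int(row["nmax_a"]) < int(row["nmax"]):
            reports.append((int(i), "nmax_a", "nmax_a must be >= nmax"))
    if reports:
        raise ValidationError(reports)
    env_cols = ["flow_velocity", "temp_start", "temp_end", "salinity", "ph",
                "dissolved_oxygen", "visibility_m", "depth_m"]
    df["env_complete"] = df[env_cols].notna().all(axis=1)
    df["reserve"] = df["reserve"].astype(bool)
    return df


def write_tags(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["tag_date"] = pd.to_datetime(out["tag_date"]).dt.date
    out.to_csv(path, index=False)


def write_receivers(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in ("op_start", "op_end"):
        out[c] = pd.to_datetime(out[c]).dt.date
    out.to_csv(path, index=False)


def write_detections(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def write_bruv(df: pd.DataFrame, path) -> None:
    out = df.drop(columns=["env_complete"], errors="ignore").copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out["reserve"] = out["reserve"].astype(int)
    out.to_csv(path, index=False)


def load_glover_fixture() -> pd.DataFrame:
    """The packaged tagging table for the 33 detected sharks at Glover's Reef.

    Carries the full tag-deployment schema plus the published per-shark
    monitoring metrics (n_days_detected, duration_days, mld_km, ri).
    Tagging coordinates are representative placements for the labelled sites,
    not surveyed positions.
    """
    with resources.as_file(resources.files("reeftrace.data") / "glover_tags.csv") as p:
        return read_tags(p)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (haversine, R = 6371.0088 km).

    Accepts scalars or numpy arrays (broadcast).  Raises ValueError for
    latitudes off the globe.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def operational_days(receivers: pd.DataFrame, receiver_id: str,
                     start=None, end=None) -> int:
    """Days a receiver was in the water, optionally clipped to [start, end].

    Intervals are closed; a receiver with intervals [a,b] and [c,d] separated
    by a gap contributes (b-a+1) + (d-c+1) days.
    """
    grp = receivers[receivers["receiver_id"].astype(str) == str(receiver_id)]
    total = 0
    for _, row in grp.iterrows():
        s, e = row["op_start"], row["op_end"]
        if start is not None:
            s = max(s, pd.Timestamp(start))
        if end is not None:
            e = min(e, pd.Timestamp(end))
        if s <= e:
            total += (e - s).days + 1
    return total
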
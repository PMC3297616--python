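"""Per-shark site-fidelity metrics and their body-size regressions.

Three metrics summarize how tightly an acoustically tagged shark sticks to
the monitored atoll:

* residency index (RI): days detected anywhere in the array divided by days
  the shark *could* have been detected (battery alive and receivers in the
  water) -- a [0, 1] standardized fidelity measure;
* minimum linear dispersal (MLD): the distance between the two furthest
  receivers at which the shark was ever detected -- a lower bound on range;
* monitoring duration: days from tagging to the last detection string
  (post-battery-expiry detections count here, but never toward RI).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import DailyPresence
from .io import haversine_km, load_glover_fixture

OCCURRENCE_BINS = ("none", "1-7", "8-14", ">14")


class UndefinedMetricError(ValueError):
    """The metric has no defined value for this shark (e.g. never detected)."""


def residency_index(presence: DailyPresence, shark_id: str) -> float:
    """Eligible detected days / eligible days; errors if no eligible days."""
    shark_id = str(shark_id)
    if shark_id not in presence.eligible_days.index:
        raise KeyError(f"unknown shark {shark_id}")
    denom = int(presence.eligible_days.loc[shark_id])
    if denom == 0:
        raise UndefinedMetricError(f"shark {shark_id} has zero eligible days")
    anyw = presence.anywhere
    num = int(((anyw["shark_id"] == shark_id) & anyw["eligible"]).sum())
    return num / denom


def minimum_linear_dispersal(presence: DailyPresence, receivers: pd.DataFrame,
                             shark_id: str) -> float:
    """Max pairwise great-circle distance over receivers with a detection.

    Zero when the shark was detected at one receiver or none: with a single
    station the dispersal floor is unresolvable.
    """
    shark_id = str(shark_id)
    seen = presence.per_receiver.loc[
        presence.per_receiver["shark_id"] == shark_id, "receiver_id"].unique()
    if len(seen) <= 1:
        return 0.0
    pos = (receivers.drop_duplicates("receiver_id")
           .set_index("receiver_id")[["lat", "lon"]])
    best = 0.0
    for a, b in combinations(seen, 2):
        d = haversine_km(pos.loc[a, "lat"], pos.loc[a, "lon"],
                         pos.loc[b, "lat"], pos.loc[b, "lon"])
        best = max(best, d)
    return best


def monitoring_duration(presence: DailyPresence, tags: pd.DataFrame,
                        shark_id: str) -> int:
    """Whole days from tagging to the last detected date (expiry ignored)."""
    shark_id = str(shark_id)
    dates = presence.anywhere.loc[presence.anywhere["shark_id"] == shark_id, "date"]
    if dates.empty:
        raise UndefinedMetricError(f"shark {shark_id} was never detected")
    tag_date = pd.to_datetime(
        tags.loc[tags["shark_id"].astype(str) == shark_id, "tag_date"].iloc[0])
    return int((dates.max() - tag_date).days)


def fidelity_table(presence: DailyPresence, tags: pd.DataFrame,
                   receivers: pd.DataFrame) -> pd.DataFrame:
    """One row of fidelity metrics per detected shark.

    Sharks with zero detections are excluded (their duration and dispersal
    are undefined), mirroring how monitoring tables are published.
    """
    rows = []
    for sid in tags["shark_id"].astype(str):
        n_days = presence.detected_days(sid)
        if n_days == 0:
            continue
        rows.append({
            "shark_id": sid,
            "n_days_detected": n_days,
            "duration_days": monitoring_duration(presence, tags, sid),
            "mld_km": minimum_linear_dispersal(presence, receivers, sid),
            "ri": residency_index(presence, sid),
        })
    return pd.DataFrame(rows)


def summarize_fidelity(metrics: pd.DataFrame, tags: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/range of each metric overall and by transmitter type."""
    df = metrics.merge(tags[["shark_id", "tag_type"]].assign(
        shark_id=tags["shark_id"].astype(str)), on="shark_id")
    out = []
    groups = [("all", df)] + [(t, g) for t, g in df.groupby("tag_type")]
    for label, g in groups:
        for col in ("ri", "mld_km", "n_days_detected", "duration_days"):
            out.append({
                "group": label, "metric": col, "n": len(g),
                "mean": g[col].mean(), "sd": g[col].std(ddof=1),
                "min": g[col].min(), "max": g[col].max(),
            })
    return pd.DataFrame(out)


def monthly_occurrence(presence: DailyPresence) -> pd.DataFrame:
    """Detected-day counts per shark per calendar month, binned.

    Counts are total (not consecutive) days per month; bins none / 1-7 /
    8-14 / >14 match the conventional occupancy shading.
    """
    anyw = presence.anywhere
    if anyw.empty:
        return pd.DataFrame(columns=["shark_id", "month", "days_detected", "bin"])
    df = anyw.assign(month=anyw["date"].dt.to_period("M"))
    counts = (df.groupby(["shark_id", "month"], as_index=False)
              .agg(days_detected=("date", "nunique")))
    counts["bin"] = pd.cut(counts["days_detected"], bins=[0, 7, 14, np.inf],
                           labels=list(OCCURRENCE_BINS[1:])).astype(str)
    counts.loc[counts["days_detected"] == 0, "bin"] = "none"
    return counts


@dataclass
class SizeRegression:
    response: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def size_regression(metrics: pd.DataFrame, tags: pd.DataFrame,
                    response: str) -> SizeRegression:
    """OLS of a fidelity metric (ri or mld_km) on total length, cm."""
    if response not in ("ri", "mld_km"):
        raise ValueError("response must be 'ri' or 'mld_km'")
    df = metrics.merge(
        tags[["shark_id", "total_length_cm"]].assign(shark_id=tags["shark_id"].astype(str)),
        on="shark_id").dropna(subset=[response, "total_length_cm"])
    if len(df) < 3:
        raise ValueError("need at least 3 sharks with a defined metric")
    x = df["total_length_cm"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: zero length variance")
    res = stats.linregress(x, df[response].to_numpy(float))
    return SizeRegression(response, res.slope, res.intercept,
                          res.rvalue ** 2, res.pvalue, len(df))


def glover_metrics() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(metrics, tags) for the packaged Glover's Reef monitoring table.

    The packaged per-shark metrics are used directly; they are the published
    values for the 33 detected sharks.
    """
    tags = load_glover_fixture()
    metrics = tags[["shark_id", "n_days_detected", "duration_days", "mld_km", "ri"]].copy()
    return metrics, tags
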
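"""Detection-string QC and daily presence.

Passive acoustic receivers log single pings that can be fabricated by signal
collisions or background noise.  Only *strings* of two or more consecutive
detections of the same transmitter at the same receiver are trusted; isolated
single detections are discarded (and counted).  Strings are then collapsed to
the day scale: the daily presence structure is the substrate for every
residency metric and model downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Two transmissions more than this far apart are not "consecutive".
#: Twice the 360 s maximum nominal pulse delay: tolerates one missed pulse.
DEFAULT_STRING_GAP_S = 720.0

#: Nominal maximum transmitter delay, seconds.
MAX_PULSE_DELAY_S = 360.0


def build_strings(detections: pd.DataFrame, string_gap_s: float = DEFAULT_STRING_GAP_S) -> pd.DataFrame:
    """Group detections into strings of >= 2 consecutive detections.

    Consecutive means successive detections of one (transmitter, receiver)
    pair separated by at most ``string_gap_s`` seconds.  Singletons are
    dropped and their count logged.  Returns one row per string with columns
    transmitter_id, receiver_id, start, end, n_detections, max_gap_s.
    """
    if string_gap_s <= 0:
        raise ValueError("string_gap_s must be positive")
    cols = ["transmitter_id", "receiver_id", "start", "end", "n_detections", "max_gap_s"]
    if detections.empty:
        return pd.DataFrame(columns=cols)
    df = detections.sort_values(["transmitter_id", "receiver_id", "timestamp"]).reset_index(drop=True)
    gap = df["timestamp"].diff().dt.total_seconds()
    new_pair = (df["transmitter_id"] != df["transmitter_id"].shift()) | (
        df["receiver_id"] != df["receiver_id"].shift())
    break_ = new_pair | (gap > string_gap_s)
    sid = break_.cumsum()
    gap_within = gap.where(~break_)
    grouped = df.assign(_gap=gap_within).groupby(sid)
    strings = grouped.agg(
        transmitter_id=("transmitter_id", "first"),
        receiver_id=("receiver_id", "first"),
        start=("timestamp", "first"),
        end=("timestamp", "last"),
        n_detections=("timestamp", "size"),
        max_gap_s=("_gap", "max"),
    )
    n_singletons = int((strings["n_detections"] == 1).sum())
    if n_singletons:
        logger.info("discarded %d singleton detection(s)", n_singletons)
    strings = strings[strings["n_detections"] >= 2].reset_index(drop=True)
    strings["max_gap_s"] = strings["max_gap_s"].fillna(0.0)
    out = strings[cols].copy()
    out.attrs["n_singletons_discarded"] = n_singletons
    return out


@dataclass
class CollisionReport:
    """Strings flagged as possible signal-collision artifacts.

    windows: receiver-time windows in which >= 3 distinct transmitters were
        detected simultaneously (the only situation the check examines).
    flagged: the subset of strings in those windows whose largest internal
        gap exceeds ``collision_lag_factor`` x the 360 s maximum delay.
    """

    windows: pd.DataFrame
    flagged: pd.DataFrame

    @property
    def empty(self) -> bool:
        return self.flagged.empty


def flag_collisions(strings: pd.DataFrame, simultaneity_window_s: float = 600.0,
                    collision_lag_factor: float = 2.0) -> CollisionReport:
    """Screen for collision-fabricated strings where >= 3 tags overlap.

    When three transmitters are heard simultaneously at one receiver, a
    "third individual" can be an artifact of two colliding pulse trains; the
    signature is a string with an unusually long internal lag given the
    transmission rate.  Strings whose intervals (padded by half the
    simultaneity window) overlap with >= 2 other transmitters at the same
    receiver are examined; those with max internal gap >
    collision_lag_factor * 360 s are flagged.
    """
    if simultaneity_window_s <= 0 or collision_lag_factor <= 0:
        raise ValueError("thresholds must be positive")
    win_cols = ["receiver_id", "window_start", "window_end", "transmitter_ids"]
    if strings.empty:
        return CollisionReport(pd.DataFrame(columns=win_cols), strings.iloc[0:0])
    pad = pd.Timedelta(seconds=simultaneity_window_s / 2.0)
    windows = []
    flagged_idx: set[int] = set()
    lag_threshold = collision_lag_factor * MAX_PULSE_DELAY_S
    for rid, grp in strings.groupby("receiver_id"):
        events = []
        for i, row in grp.iterrows():
            events.append((row["start"] - pad, 1, i, row["transmitter_id"]))
            events.append((row["end"] + pad, -1, i, row["transmitter_id"]))
        events.sort(key=lambda e: (e[0], -e[1]))
        active: dict[int, str] = {}
        for t, kind, i, tid in events:
            if kind == 1:
                active[i] = tid
                tids = set(active.values())
                if len(tids) >= 3:
                    sub = grp.loc[list(active.keys())]
                    windows.append({
                        "receiver_id": rid,
                        "window_start": sub["start"].min(),
                        "window_end": sub["end"].max(),
                        "transmitter_ids": sorted(tids),
                    })
                    flagged_idx.update(
                        j for j in active if grp.loc[j, "max_gap_s"] > lag_threshold)
            else:
                active.pop(i, None)
    windows_df = pd.DataFrame(windows, columns=win_cols)
    flagged = strings.loc[sorted(flagged_idx)]
    return CollisionReport(windows_df, flagged)


@dataclass
class DailyPresence:
    """Shark x receiver x day detection indicators with an eligibility mask.

    per_receiver: rows (shark_id, receiver_id, date) for detected days only.
    anywhere: rows (shark_id, date, eligible) for days with any detection;
        ``eligible`` is False for detections logged after the transmitter's
        nominal battery expiry or outside array coverage (they are retained
        -- monitoring duration uses them -- but excluded from the residency
        index).
    eligible_days: per shark, the number of days with an active battery and
        >= 1 operational receiver (the residency-index denominator).
    tag_window: per shark (tag_date, expiry_date).
    """

    per_receiver: pd.DataFrame
    anywhere: pd.DataFrame
    eligible_days: pd.Series
    tag_window: pd.DataFrame

    def detected_days(self, shark_id: str, receiver_id: str | None = None) -> int:
        if receiver_id is None:
            return int((self.anywhere["shark_id"] == str(shark_id)).sum())
        m = (self.per_receiver["shark_id"] == str(shark_id)) & (
            self.per_receiver["receiver_id"] == str(receiver_id))
        return int(m.sum())


def _string_dates(strings: pd.DataFrame) -> pd.DataFrame:
    """Expand each string to the calendar dates it overlaps (usually one)."""
    recs = []
    starts = strings["start"].dt.normalize()
    ends = strings["end"].dt.normalize()
    for (tid, rid, s, e) in zip(strings["transmitter_id"], strings["receiver_id"], starts, ends):
        for d in pd.date_range(s, e, freq="D"):
            recs.append((tid, rid, d))
    return pd.DataFrame(recs, columns=["transmitter_id", "receiver_id", "date"]).drop_duplicates()


def array_operational_dates(receivers: pd.DataFrame) -> pd.DatetimeIndex:
    """Dates on which at least one receiver interval is active."""
    dates: set[pd.Timestamp] = set()
    for _, row in receivers.iterrows():
        dates.update(pd.date_range(row["op_start"], row["op_end"], freq="D"))
    return pd.DatetimeIndex(sorted(dates))


def daily_presence(strings: pd.DataFrame, tags: pd.DataFrame,
                   receivers: pd.DataFrame) -> DailyPresence:
    """Collapse QC'd strings to day-scale presence with eligibility.

    A shark is "present" at a receiver on every calendar date its strings
    overlap (a string spanning midnight scores both dates).  A date is
    eligible for a shark when its battery window (tag_date .. tag_date +
    battery_days) covers it and at least one receiver in the array is
    operational.  Post-expiry detections are retained with eligible=False.
    """
    tags = tags.copy()
    tags["shark_id"] = tags["shark_id"].astype(str)
    tags["transmitter_id"] = tags["transmitter_id"].astype(str)
    tag_date = pd.to_datetime(tags["tag_date"])
    expiry = tag_date + pd.to_timedelta(tags["battery_days"], unit="D")
    tag_window = pd.DataFrame({
        "shark_id": tags["shark_id"], "tag_date": tag_date, "expiry": expiry,
    }).set_index("shark_id")
    tid_to_shark = dict(zip(tags["transmitter_id"], tags["shark_id"]))

    array_dates = array_operational_dates(receivers)

    if strings.empty:
        per_receiver = pd.DataFrame(columns=["shark_id", "receiver_id", "date", "eligible"])
        anywhere = pd.DataFrame(columns=["shark_id", "date", "eligible"])
    else:
        unknown = set(strings["transmitter_id"]) - set(tid_to_shark)
        if unknown:
            raise KeyError(f"strings reference unknown transmitter(s): {sorted(unknown)}")
        per_receiver = _string_dates(strings)
        per_receiver["shark_id"] = per_receiver["transmitter_id"].map(tid_to_shark)
        per_receiver = per_receiver.drop(columns="transmitter_id")
        w = tag_window.loc[per_receiver["shark_id"]]
        in_battery = (per_receiver["date"].values >= w["tag_date"].values) & (
            per_receiver["date"].values <= w["expiry"].values)
        per_receiver["eligible"] = in_battery & per_receiver["date"].isin(array_dates).values
        anywhere = (per_receiver.groupby(["shark_id", "date"], as_index=False)
                    .agg(eligible=("eligible", "any")))

    n_eligible = {}
    for sid, row in tag_window.iterrows():
        n_eligible[sid] = int(((array_dates >= row["tag_date"]) &
                               (array_dates <= row["expiry"])).sum())
    eligible_days = pd.Series(n_eligible, name="eligible_days")
    eligible_days.index.name = "shark_id"
    return DailyPresence(per_receiver[["shark_id", "receiver_id", "date", "eligible"]],
                         anywhere, eligible_days, tag_window.reset_index())
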
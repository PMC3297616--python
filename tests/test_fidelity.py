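"""Residency index, minimum linear dispersal, duration and size regressions."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import reeftrace as rt
from reeftrace.fidelity import (
    UndefinedMetricError, fidelity_table, minimum_linear_dispersal,
    monitoring_duration, monthly_occurrence, residency_index, size_regression,
    summarize_fidelity,
)
from reeftrace.filtering import DailyPresence
from reeftrace.io import haversine_km


def presence_from_days(day_map, tag_date="2005-01-01", battery=365,
                       eligible_override=None):
    """Build a DailyPresence directly from {shark: {receiver: [day offsets]}}."""
    t0 = pd.Timestamp(tag_date)
    per, anyw = [], {}
    for sid, recs in day_map.items():
        for rid, offs in recs.items():
            for o in offs:
                d = t0 + pd.Timedelta(days=int(o))
                eligible = o <= battery
                per.append({"shark_id": sid, "receiver_id": rid, "date": d,
                            "eligible": eligible})
                key = (sid, d)
                anyw[key] = anyw.get(key, False) or eligible
    per_df = pd.DataFrame(per, columns=["shark_id", "receiver_id", "date", "eligible"])
    any_df = pd.DataFrame([{"shark_id": s, "date": d, "eligible": e}
                           for (s, d), e in anyw.items()],
                          columns=["shark_id", "date", "eligible"])
    n_elig = eligible_override or {}
    elig = pd.Series({s: n_elig.get(s, battery + 1) for s in day_map},
                     name="eligible_days")
    elig.index.name = "shark_id"
    window = pd.DataFrame({"shark_id": list(day_map),
                           "tag_date": t0,
                           "expiry": t0 + pd.Timedelta(days=battery)})
    return DailyPresence(per_df, any_df, elig, window)


def receivers_at(coords):
    return pd.DataFrame([
        {"receiver_id": rid, "lat": lat, "lon": lon, "habitat": "ocean_reef",
         "depth_m": 20.0, "op_start": pd.Timestamp("2004-01-01"),
         "op_end": pd.Timestamp("2008-01-01")}
        for rid, lat, lon in coords])


class TestResidencyIndex:
    def test_every_day_detected_gives_one(self):
        pres = presence_from_days({"S1": {"R1": list(range(366))}})
        assert residency_index(pres, "S1") == 1.0

    def test_never_detected_gives_zero(self):
        pres = presence_from_days({"S1": {"R1": []}})
        assert residency_index(pres, "S1") == 0.0

    def test_zero_eligible_days_is_undefined(self):
        pres = presence_from_days({"S1": {"R1": []}}, eligible_override={"S1": 0})
        with pytest.raises(UndefinedMetricError):
            residency_index(pres, "S1")

    def test_duplicate_detections_within_day_do_not_inflate(self):
        a = presence_from_days({"S1": {"R1": [0, 1, 2]}})
        b = presence_from_days({"S1": {"R1": [0, 1, 2], "R2": [0, 1, 2]}})
        assert residency_index(a, "S1") == residency_index(b, "S1")

    def test_published_rounding_example(self):
        # 361 detected of 366 eligible days prints as 0.99
        pres = presence_from_days({"S1": {"R1": list(range(361))}})
        assert round(residency_index(pres, "S1"), 2) == 0.99

    def test_mean_ri_recovers_daily_detection_rate(self):
        # E[RI] = p for Bernoulli(p) days; 200 replicate sharks x 365 days
        rng = np.random.default_rng(11)
        p = 0.3
        day_map = {f"S{i}": {"R1": list(np.flatnonzero(rng.random(365) < p))}
                   for i in range(200)}
        pres = presence_from_days(day_map, eligible_override={f"S{i}": 365 for i in range(200)})
        ris = [residency_index(pres, f"S{i}") for i in range(200)]
        se = np.sqrt(p * (1 - p) / 365 / 200)
        assert abs(np.mean(ris) - p) < 3 * se
        assert all(0.0 <= r <= 1.0 for r in ris)


class TestMLD:
    def test_single_receiver_is_zero(self):
        recs = receivers_at([("R1", 0.0, 0.0)])
        pres = presence_from_days({"S1": {"R1": [0, 1]}})
        assert minimum_linear_dispersal(pres, recs, "S1") == 0.0

    def test_three_collinear_receivers(self):
        recs = receivers_at([("R1", 0.0, 0.0), ("R2", 0.0, 0.01), ("R3", 0.0, 0.02)])
        pres = presence_from_days({"S1": {"R1": [0], "R2": [1], "R3": [2]}})
        d = minimum_linear_dispersal(pres, recs, "S1")
        assert d == pytest.approx(haversine_km(0, 0, 0, 0.02), abs=1e-9)
        assert d == pytest.approx(2.224, abs=0.001)

    def test_matches_brute_force_on_random_sharks(self):
        rng = np.random.default_rng(4)
        coords = [(f"R{i}", rng.uniform(16.6, 16.9), rng.uniform(-87.9, -87.7))
                  for i in range(8)]
        recs = receivers_at(coords)
        for rep in range(10):
            visited = rng.choice(8, size=rng.integers(1, 9), replace=False)
            pres = presence_from_days(
                {"S1": {f"R{i}": [int(rng.integers(0, 300))] for i in visited}})
            got = minimum_linear_dispersal(pres, recs, "S1")
            pos = {rid: (lat, lon) for rid, lat, lon in coords}
            want = max((haversine_km(*pos[f"R{i}"], *pos[f"R{j}"])
                        for i, j in combinations(visited, 2)), default=0.0)
            assert got == pytest.approx(want, abs=1e-12)

    def test_visit_frequency_is_irrelevant(self):
        recs = receivers_at([("R1", 0.0, 0.0), ("R2", 0.0, 0.05)])
        a = presence_from_days({"S1": {"R1": [0], "R2": [1]}})
        b = presence_from_days({"S1": {"R1": list(range(100)), "R2": [1, 2, 3]}})
        assert minimum_linear_dispersal(a, recs, "S1") == \
            minimum_linear_dispersal(b, recs, "S1")


class TestDuration:
    def test_last_detection_on_tag_date(self):
        pres = presence_from_days({"S1": {"R1": [0]}})
        tags = pd.DataFrame({"shark_id": ["S1"], "tag_date": [pd.Timestamp("2005-01-01")]})
        assert monitoring_duration(pres, tags, "S1") == 0

    def test_never_detected_is_undefined(self):
        pres = presence_from_days({"S1": {"R1": []}})
        tags = pd.DataFrame({"shark_id": ["S1"], "tag_date": [pd.Timestamp("2005-01-01")]})
        with pytest.raises(UndefinedMetricError):
            monitoring_duration(pres, tags, "S1")

    def test_spans_battery_expiry(self):
        # tagged 2005-05-24, last string 2006-12-29 -> 584 days
        pres = presence_from_days({"S1": {"R1": [0, 584]}}, tag_date="2005-05-24",
                                  battery=540)
        tags = pd.DataFrame({"shark_id": ["S1"], "tag_date": [pd.Timestamp("2005-05-24")]})
        assert monitoring_duration(pres, tags, "S1") == 584


class TestMonthlyOccurrence:
    @pytest.mark.parametrize("n_days,expected", [(7, "1-7"), (8, "8-14"), (15, ">14")])
    def test_bin_edges(self, n_days, expected):
        pres = presence_from_days({"S1": {"R1": list(range(n_days))}})
        occ = monthly_occurrence(pres)
        assert occ["bin"].iloc[0] == expected

    def test_month_with_no_detections_absent_from_table(self):
        pres = presence_from_days({"S1": {"R1": [0, 70]}})
        occ = monthly_occurrence(pres)
        months = occ[occ["shark_id"] == "S1"]["month"].astype(str).tolist()
        assert months == ["2005-01", "2005-03"]


class TestSizeRegression:
    def test_exact_linear_relationship(self, glover):
        metrics, tags = glover
        fake = metrics.copy()
        tl = tags.set_index(tags["shark_id"].astype(str))["total_length_cm"]
        fake["ri"] = 0.001 * tl.loc[fake["shark_id"]].to_numpy()
        res = size_regression(fake, tags, "ri")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_design_rejected(self, glover):
        metrics, tags = glover
        flat = tags.copy()
        flat["total_length_cm"] = 100.0
        with pytest.raises(ValueError, match="variance"):
            size_regression(metrics, flat, "ri")

    def test_needs_three_sharks(self, glover):
        metrics, tags = glover
        with pytest.raises(ValueError, match="3 sharks"):
            size_regression(metrics.head(2), tags, "ri")


class TestSummaries:
    def test_single_shark_mean_is_its_value(self, glover):
        metrics, tags = glover
        one = metrics.head(1)
        summ = summarize_fidelity(one, tags)
        row = summ[(summ["group"] == "all") & (summ["metric"] == "ri")].iloc[0]
        assert row["mean"] == one["ri"].iloc[0]

    def test_extra_receiver_without_detections_changes_nothing(self, pipeline, sim):
        _, presence, _ = pipeline
        base = fidelity_table(presence, sim.tags, sim.receivers)
        extra = pd.concat([sim.receivers, pd.DataFrame([{
            "receiver_id": "R99", "lat": 16.9, "lon": -87.5, "habitat": "ocean_reef",
            "depth_m": 20.0, "op_start": pd.Timestamp("2004-05-01"),
            "op_end": pd.Timestamp("2008-05-01")}])], ignore_index=True)
        again = fidelity_table(presence, sim.tags, extra)
        pd.testing.assert_frame_equal(base, again)
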
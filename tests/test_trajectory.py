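"""Fix ingestion, trip segmentation, trip metrics and activity budgets."""

import numpy as np
import pandas as pd
import pytest

from dualforage.geo import haversine_km
from dualforage.trajectory import (Trip, classify_destination, diel_budget,
                                   metrics_frame, read_fixes, segment_trips,
                                   summarize_trips, trip_metrics,
                                   variance_ratio_test)

from conftest import COLONY, T0, make_trip, straight_out_back

HEADER = "id,timestamp_utc,lon,lat,speed_kmh\n"


def _write(tmp_path, body):
    p = tmp_path / "fixes.csv"
    p.write_text(HEADER + body)
    return p


class TestReadFixes:
    def test_well_formed_rows_sorted(self, tmp_path):
        p = _write(tmp_path,
                   "g1,2010-05-17T00:06:00Z,7.76,53.78,10\n"
                   "g1,2010-05-17T00:00:00Z,7.76,53.78,10\n"
                   "g1,2010-05-17T00:03:00Z,7.76,53.78,10\n")
        series, report = read_fixes(p)
        assert len(series["g1"]) == 3
        assert series["g1"]["timestamp_utc"].is_monotonic_increasing
        assert report["speed_filtered"] == 0

    def test_duplicate_timestamp_collapsed(self, tmp_path):
        p = _write(tmp_path,
                   "g1,2010-05-17T00:00:00Z,7.76,53.78,10\n"
                   "g1,2010-05-17T00:00:00Z,7.90,53.78,10\n"
                   "g1,2010-05-17T00:03:00Z,7.76,53.78,10\n")
        series, report = read_fixes(p)
        assert len(series["g1"]) == 2
        assert report["duplicate_timestamps"] == 1
        # first occurrence kept
        assert series["g1"]["lon"].iloc[0] == pytest.approx(7.76)

    def test_implausible_jump_dropped(self, tmp_path):
        # ~100 km north in 3 min implies ~2000 km/h (haversine hand-check)
        far_lat = 53.78 + 100.0 / 111.19
        assert haversine_km(7.76, 53.78, 7.76, far_lat) == pytest.approx(100, abs=0.1)
        p = _write(tmp_path,
                   "g1,2010-05-17T00:00:00Z,7.76,53.78,10\n"
                   f"g1,2010-05-17T00:03:00Z,7.76,{far_lat:.6f},10\n"
                   "g1,2010-05-17T00:06:00Z,7.76,53.781,10\n")
        series, report = read_fixes(p, max_speed_kmh=150.0)
        assert len(series["g1"]) == 2
        assert report["speed_filtered"] == 1

    def test_malformed_row_skipped(self, tmp_path):
        p = _write(tmp_path,
                   "g1,2010-05-17T00:00:00Z,7.76,53.78,10\n"
                   "g1,not-a-time,7.76,53.78,10\n"
                   "g1,2010-05-17T00:03:00Z,oops,53.78,10\n")
        series, report = read_fixes(p)
        assert len(series["g1"]) == 1
        assert report["malformed"] == 2

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(HEADER)
        with pytest.raises(ValueError):
            read_fixes(p)


class TestSegmentTrips:
    def test_never_leaving_buffer_yields_no_trips(self, proj):
        trip = make_trip(proj, [(0.0, 0.1), (0.1, 0.2), (0.0, 0.3)],
                         [0.0, 0.05, 0.1])
        assert segment_trips(trip.fixes, "b", COLONY, buffer_km=0.5) == []

    def test_single_excursion_bounded_by_crossing_fixes(self, proj):
        # dwell, out to 20 km over ~1 h, dwell again
        ys = [0.1, 0.1, 2, 8, 14, 20, 14, 8, 2, 0.1, 0.1]
        t = np.arange(len(ys)) * 0.25
        trip_fix = make_trip(proj, [(0.0, y) for y in ys], t).fixes
        trips = segment_trips(trip_fix, "b", COLONY, buffer_km=0.5,
                              min_duration_h=0.5)
        assert len(trips) == 1
        tr = trips[0]
        assert tr.complete
        # extended to the bounding inside-buffer fixes
        assert tr.fixes["timestamp_utc"].iloc[0] == trip_fix["timestamp_utc"].iloc[1]
        assert tr.fixes["timestamp_utc"].iloc[-1] == trip_fix["timestamp_utc"].iloc[-2]

    def test_two_excursions_split_by_colony_dwell(self, proj):
        ys = [0.1, 5, 10, 5] + [0.1] * 5 + [5, 10, 5, 0.1]
        t = np.arange(len(ys)) * 0.25  # dwell gap ~1 h
        trips = segment_trips(make_trip(proj, [(0.0, y) for y in ys], t).fixes,
                              "b", COLONY, buffer_km=0.5, min_duration_h=0.5)
        assert len(trips) == 2

    def test_short_run_discarded(self, proj):
        ys = [0.1, 5, 0.1]
        t = [0.0, 0.05, 0.1]  # 6-minute excursion
        trips = segment_trips(make_trip(proj, [(0.0, y) for y in ys], t).fixes,
                              "b", COLONY, buffer_km=0.5, min_duration_h=0.5)
        assert trips == []

    def test_recovers_simulated_trip_count(self, small_sim, small_cfg):
        total = 0
        for ind, df in small_sim.fixes.items():
            total += len(segment_trips(df, ind, small_cfg.colony_lonlat,
                                       buffer_km=0.5, min_duration_h=0.5))
        assert total == len(small_sim.truth)


class TestTripMetrics:
    def test_straight_out_and_back_identity(self, proj):
        m = trip_metrics(straight_out_back(proj, range_km=30.0), COLONY)
        assert m.foraging_range_km == pytest.approx(30.0, abs=0.05)
        assert m.total_distance_km == pytest.approx(60.0, abs=0.1)
        assert m.straightness == pytest.approx(1.0, abs=1e-3)

    def test_loop_straightness_0p6(self, proj):
        # out 30 km north, back along a 70 km zigzag: straightness 60/100
        out_y = np.arange(0.0, 30.0 + 1e-9, 1.0)
        out = [(0.0, y) for y in out_y]
        leg = 7.0 / 3.0
        dx = np.sqrt(leg ** 2 - 1.0)
        back = []
        x = 0.0
        for k in range(30):
            x = dx if k % 2 == 0 else 0.0
            back.append((x, 29.0 - k))
        pts = out + back
        t = np.arange(len(pts)) * 0.02
        m = trip_metrics(make_trip(proj, pts, t), COLONY)
        assert m.total_distance_km == pytest.approx(100.0, abs=0.05)
        assert m.foraging_range_km == pytest.approx(30.0, abs=0.05)
        assert m.straightness == pytest.approx(0.600, abs=1e-3)

    def test_single_fix_trip_rejected(self, proj):
        lon, lat = proj.inverse(0.0, 5.0)
        fixes = pd.DataFrame({"timestamp_utc": [T0], "lon": [float(lon)],
                              "lat": [float(lat)], "speed_kmh": [10.0]})
        with pytest.raises(ValueError):
            Trip(individual_id="b", fixes=fixes, start=T0, end=T0, complete=False)

    def test_collinear_insertion_leaves_total_distance(self, proj):
        coarse = straight_out_back(proj, range_km=30.0, step_km=5.0)
        fine = straight_out_back(proj, range_km=30.0, step_km=1.0)
        a = trip_metrics(coarse, COLONY).total_distance_km
        b = trip_metrics(fine, COLONY).total_distance_km
        assert abs(a - b) / a < 1e-6

    def test_range_never_exceeds_total(self, small_sim, small_cfg):
        for ind, df in small_sim.fixes.items():
            for tr in segment_trips(df, ind, small_cfg.colony_lonlat):
                m = trip_metrics(tr, small_cfg.colony_lonlat)
                assert m.foraging_range_km <= m.total_distance_km
                assert 0 < m.straightness <= 1.0


class TestClassifyDestination:
    def _trip(self, proj, y_dest, speeds_slow=True):
        ys = [0.1, y_dest / 2, y_dest, y_dest, y_dest, y_dest / 2, 0.1]
        speeds = [40, 40, 5, 5, 5, 40, 40] if speeds_slow else [40] * 7
        t = np.arange(7) * 0.3
        return make_trip(proj, [(0.0, y) for y in ys], t, speeds=speeds)

    def test_all_dwell_over_sea(self, proj, mask):
        assert classify_destination(self._trip(proj, 25.0), mask) == "sea"

    def test_all_dwell_over_mainland(self, proj, mask):
        assert classify_destination(self._trip(proj, -30.0), mask) == "inland"

    def test_even_split_is_mixed(self, proj, mask):
        pts = [(0.0, 0.1), (0.0, 20.0), (0.0, 20.0), (0.0, -30.0),
               (0.0, -30.0), (0.0, 0.1)]
        speeds = [40, 5, 5, 5, 5, 40]
        trip = make_trip(proj, pts, np.arange(6) * 0.5, speeds=speeds)
        assert classify_destination(trip, mask) == "mixed"

    def test_no_dwell_falls_back_to_most_distant_fix(self, proj, mask):
        trip = self._trip(proj, 25.0, speeds_slow=False)
        assert classify_destination(trip, mask) == "sea"


class TestSummaries:
    def test_partition_percentages(self):
        rows = []
        for dest, n in (("sea", 52), ("inland", 47), ("mixed", 7), ("island", 2)):
            for _ in range(n):
                rows.append({"individual_id": "x", "duration_h": 1.0,
                             "foraging_range_km": 10.0,
                             "total_distance_km": 25.0, "straightness": 0.8,
                             "destination": dest, "complete": True})
        s = summarize_trips(pd.DataFrame(rows)).set_index("destination")
        assert s.loc["sea", "pct"] == 48.1
        assert s.loc["inland", "pct"] == 43.5
        assert s.loc["mixed", "pct"] == 6.5
        assert s.loc["island", "pct"] == 1.9
        assert s["n"].drop("all").sum() == 108

    def test_single_trip_has_no_se(self):
        df = pd.DataFrame([{"individual_id": "x", "duration_h": 2.0,
                            "foraging_range_km": 10.0, "total_distance_km": 25.0,
                            "straightness": 0.8, "destination": "sea",
                            "complete": True}])
        s = summarize_trips(df)
        assert np.isnan(s["duration_h_se"]).all()

    def test_identical_trips_have_zero_se(self):
        df = pd.DataFrame([{"individual_id": "x", "duration_h": 2.0,
                            "foraging_range_km": 10.0, "total_distance_km": 25.0,
                            "straightness": 0.8, "destination": "sea",
                            "complete": True}] * 4)
        s = summarize_trips(df)
        assert (s["duration_h_se"] == 0).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_trips(pd.DataFrame())


class TestDielBudget:
    def test_afternoon_land_trip(self, proj, mask):
        # land dwell 12:00-18:00 local (10:00-16:00 UTC)
        t = 10.0 + np.arange(0, 6.01, 0.5)
        pts = [(0.0, -30.0)] * len(t)
        trip = make_trip(proj, pts, t, speeds=np.full(len(t), 5.0))
        out = diel_budget([trip], mask, utc_offset_h=2.0).set_index("bin")
        assert out.loc[13, "land_share_mean"] == 1.0
        assert 2 not in out.index

    def test_all_sea_data(self, proj, mask):
        t = np.arange(0, 3.01, 0.25)
        trip = make_trip(proj, [(0.0, 20.0)] * len(t), t,
                         speeds=np.full(len(t), 5.0))
        out = diel_budget([trip], mask, utc_offset_h=2.0)
        assert (out["sea_share_mean"] == 1.0).all()

    def test_simulated_land_use_respects_darkness(self, small_sim, small_cfg, mask):
        trips = []
        for ind, df in small_sim.fixes.items():
            trips.extend(segment_trips(df, ind, small_cfg.colony_lonlat))
        out = diel_budget(trips, mask,
                          utc_offset_h=small_cfg.utc_offset_h).set_index("bin")
        night = [h for h in (23, 0, 1, 2, 3) if h in out.index]
        assert night, "expected some night-time fixes"
        assert (out.loc[night, "land_share_mean"] == 0).all()

    def test_weekday_budget_bins(self, proj, mask):
        t = np.arange(0, 3.01, 0.5)
        trip = make_trip(proj, [(0.0, 20.0)] * len(t), t,
                         speeds=np.full(len(t), 5.0))
        out = diel_budget([trip], mask, by="weekday")
        assert set(out["bin"]) <= set(range(7))


class TestVarianceRatio:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        F, p = variance_ratio_test(a, a)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_swap_inverts_f_same_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(scale=2.0, size=25)
        F1, p1 = variance_ratio_test(a, b)
        F2, p2 = variance_ratio_test(b, a)
        assert F2 == pytest.approx(1.0 / F1)
        assert p1 == pytest.approx(p2)

    def test_fourfold_variance(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=5000)
        a = 2.0 * b  # variance exactly 4x
        F, p = variance_ratio_test(a, b)
        assert F == pytest.approx(4.0)
        assert p < 1e-10

    def test_zero_denominator_variance_errors(self):
        with pytest.raises(ValueError):
            variance_ratio_test([1.0, 2.0], [3.0, 3.0])
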
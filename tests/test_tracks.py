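"""Homing-index unit tests against hand-constructed flights and oracles."""
import math

import numpy as np
import pandas as pd
import pytest

from olfnav.geo import GeoPoint, destination_point, haversine_distance, initial_bearing
from olfnav.tracks import (
    IndicesConfig,
    Track,
    compute_indices,
    homing_efficiency_index,
    indices_table,
    initial_orientation,
    mean_aggregate_azimuth_penalty,
    segment_steps,
)

from conftest import aimed_track_fixes, straight_track_fixes

T0 = "2016-07-04T08:00:00"


def make_track(fixes, release, home, bird_id="b1", t0=T0) -> Track:
    return Track(bird_id=bird_id, release_site=release, home=home,
                 release_time=pd.Timestamp(t0), fixes=fixes)


class TestSegmentSteps:
    def test_two_fix_arithmetic(self, home):
        q = destination_point(home, 90.0, 1.0)
        fixes = pd.DataFrame(
            {
                "time": pd.to_datetime([T0, "2016-07-04T08:06:00"]),
                "lat": [home.lat, q.lat],
                "lon": [home.lon, q.lon],
            }
        )
        track = make_track(fixes, home, q)
        steps = segment_steps(track)
        assert len(steps) == 1
        assert steps.loc[0, "length_km"] == pytest.approx(1.0, abs=1e-9)
        assert steps.loc[0, "duration_s"] == 360.0
        assert steps.loc[0, "speed_kmh"] == pytest.approx(10.0, abs=1e-6)

    def test_duplicate_fix_flagged_zero_length(self, home):
        q = destination_point(home, 0.0, 1.0)
        fixes = pd.DataFrame(
            {
                "time": pd.to_datetime([T0, "2016-07-04T08:00:10", "2016-07-04T08:00:20"]),
                "lat": [home.lat, home.lat, q.lat],
                "lon": [home.lon, home.lon, q.lon],
            }
        )
        steps = segment_steps(make_track(fixes, home, q))
        assert bool(steps.loc[0, "zero_length"])
        assert math.isnan(steps.loc[0, "heading_deg"])
        assert not bool(steps.loc[1, "zero_length"])

    def test_nonincreasing_timestamps_rejected(self, home):
        fixes = pd.DataFrame(
            {
                "time": pd.to_datetime([T0, T0]),
                "lat": [home.lat, home.lat + 0.01],
                "lon": [home.lon, home.lon],
            }
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            make_track(fixes, home, home)

    def test_length_sum_matches_pairwise_oracle(self, home):
        rng = np.random.default_rng(3)
        lat = home.lat + np.cumsum(rng.normal(0, 0.002, 50))
        lon = home.lon + np.cumsum(rng.normal(0, 0.002, 50))
        fixes = pd.DataFrame(
            {
                "time": pd.Timestamp(T0) + pd.to_timedelta(np.arange(50) * 10, unit="s"),
                "lat": lat,
                "lon": lon,
            }
        )
        steps = segment_steps(make_track(fixes, home, home))
        oracle = sum(
            haversine_distance(GeoPoint(lat[i], lon[i]), GeoPoint(lat[i + 1], lon[i + 1]))
            for i in range(49)
        )
        assert steps["length_km"].sum() == pytest.approx(oracle, rel=1e-12)


class TestInitialOrientation:
    def test_straight_east(self, home):
        fixes = straight_track_fixes(home, 90.0, 60.0, 120)
        mv = initial_orientation(make_track(fixes, home, home))
        assert mv.direction == pytest.approx(90.0, abs=0.2)
        assert mv.r == pytest.approx(1.0, abs=1e-6)

    def test_alternating_headings_inconsistent(self, home):
        pts = [home]
        for i in range(40):
            pts.append(destination_point(pts[-1], 0.0 if i % 2 == 0 else 180.0, 0.2))
        fixes = pd.DataFrame(
            {
                "time": pd.Timestamp(T0) + pd.to_timedelta(np.arange(41) * 10, unit="s"),
                "lat": [p.lat for p in pts],
                "lon": [p.lon for p in pts],
            }
        )
        track = make_track(fixes, home, destination_point(home, 90, 50))
        mv = initial_orientation(track)
        assert mv.r < 0.1
        assert not compute_indices(track).consistent

    def test_von_mises_heading_recovery(self, release_site, home):
        rng = np.random.default_rng(123)
        headings = (np.degrees(rng.vonmises(0.0, 2.0, 200)) + 270.0) % 360.0
        pts = [release_site]
        for h in headings:
            pts.append(destination_point(pts[-1], h, 0.15))
        fixes = pd.DataFrame(
            {
                "time": pd.Timestamp(T0) + pd.to_timedelta(np.arange(201) * 10, unit="s"),
                "lat": [p.lat for p in pts],
                "lon": [p.lon for p in pts],
            }
        )
        mv = initial_orientation(make_track(fixes, release_site, home))
        from olfnav.geo import angular_difference

        assert angular_difference(mv.direction, 270.0) < 10.0

    def test_infinite_radius_equals_global_mean(self, release_site, home):
        from olfnav.geo import circular_mean

        fixes = aimed_track_fixes(release_site, home, 60.0, 200)
        track = make_track(fixes, release_site, home)
        steps = segment_steps(track)
        mv_inf = initial_orientation(track, radius_km=math.inf)
        expect = circular_mean(steps.loc[~steps.zero_length, "heading_deg"].to_numpy())
        assert mv_inf.direction == pytest.approx(expect.direction, abs=1e-9)
        assert mv_inf.r == pytest.approx(expect.r, abs=1e-12)

    def test_no_qualifying_steps_raises(self, home):
        fixes = straight_track_fixes(destination_point(home, 0, 50), 0.0, 60.0, 5)
        track = make_track(fixes, home, home)  # release 50 km from first fix
        with pytest.raises(ValueError, match="no qualifying steps"):
            initial_orientation(track, radius_km=10.0)


class TestHEI:
    def test_straight_home_flight_is_one(self, home):
        release = destination_point(home, 61.0, 20.0)
        # reaches home exactly in ~20 min of active flight, inside the window
        fixes = aimed_track_fixes(release, home, 60.0, 130, stop_at_target=True)
        hei = homing_efficiency_index(
            make_track(fixes, release, home), home_radius_km=0.0
        )
        assert hei == pytest.approx(1.0, abs=1e-6)

    def test_straight_away_construction(self, home):
        """b=60 km, 30 km straight away from home: HEI = 1*(60-90)/60 = -0.5."""
        release = destination_point(home, 90.0, 60.0)
        away = (initial_bearing(release, home) + 180.0) % 360.0
        fixes = straight_track_fixes(release, away, 60.0, 181)  # 30 min -> 30 km
        hei, comp = homing_efficiency_index(
            make_track(fixes, release, home), return_components=True
        )
        assert comp["b"] == pytest.approx(60.0, abs=1e-6)
        assert comp["a"] == pytest.approx(30.0, abs=0.05)
        assert comp["c"] == pytest.approx(90.0, abs=0.05)
        assert hei == pytest.approx(-0.5, abs=2e-3)

    def test_active_clock_ignores_slow_segments_but_keeps_length(self, home):
        release = destination_point(home, 90.0, 150.0)  # far: no home arrival
        n = 400
        fixes = aimed_track_fixes(release, home, 60.0, n)
        # logger says the first 10 minutes were below the activity threshold
        speed = np.full(n, 60.0)
        speed[:60] = 5.0
        fixes["speed_kmh"] = speed
        track = make_track(fixes, release, home)
        _, comp = homing_efficiency_index(
            track, active_minutes=50.0, return_components=True
        )
        # clock: 60 inactive fixes + 300 active steps of 10 s = 50 min
        assert comp["truncation_index"] == 360
        steps = segment_steps(track)
        assert comp["l"] == pytest.approx(steps["length_km"][:360].sum(), rel=1e-12)

    def test_component_oracle_on_meandering_tracks(self, home):
        rng = np.random.default_rng(9)
        release = destination_point(home, 61.0, 59.9)
        for _ in range(20):
            n = 80
            headings = rng.uniform(0, 360, n - 1)
            pts = [release]
            for h in headings:
                pts.append(destination_point(pts[-1], h, rng.uniform(0.05, 0.3)))
            fixes = pd.DataFrame(
                {
                    "time": pd.Timestamp(T0) + pd.to_timedelta(np.arange(n) * 10, unit="s"),
                    "lat": [p.lat for p in pts],
                    "lon": [p.lon for p in pts],
                }
            )
            track = make_track(fixes, release, home)
            hei, comp = homing_efficiency_index(track, return_components=True)
            k = comp["truncation_index"]
            a = haversine_distance(release, pts[k])
            l = sum(haversine_distance(pts[i], pts[i + 1]) for i in range(k))
            b = haversine_distance(release, home)
            c = haversine_distance(pts[k], home)
            assert hei == pytest.approx((a / l) * (b - c) / b, rel=1e-10)

    def test_zero_beeline_rejected(self, home):
        fixes = straight_track_fixes(home, 90.0, 60.0, 5)
        with pytest.raises(ValueError, match="b = 0"):
            homing_efficiency_index(make_track(fixes, home, home))


class TestMAAP:
    def test_great_circle_home_flight_near_zero(self, home):
        release = destination_point(home, 61.0, 59.9)
        fixes = aimed_track_fixes(release, home, 15.0, 3 * 360 + 1)  # 3 h at 15 km/h
        maap = mean_aggregate_azimuth_penalty(make_track(fixes, release, home))
        assert maap == pytest.approx(0.0, abs=1.0)

    def test_constant_offset_flight_is_ninety(self, home):
        release = destination_point(home, 61.0, 59.9)
        # hourly fixes, each displaced 90 deg off the instantaneous home azimuth
        pts = [release]
        times = [pd.Timestamp(T0)]
        for k in range(4):
            b = (initial_bearing(pts[-1], home) + 90.0) % 360.0
            pts.append(destination_point(pts[-1], b, 5.0))
            times.append(times[-1] + pd.Timedelta(hours=1))
        fixes = pd.DataFrame(
            {"time": times, "lat": [p.lat for p in pts], "lon": [p.lon for p in pts]}
        )
        maap = mean_aggregate_azimuth_penalty(make_track(fixes, release, home))
        assert maap == pytest.approx(90.0, abs=0.5)

    def test_matches_hand_rolled_hourly_oracle(self, home):
        from olfnav.geo import angular_difference, bearing_deg

        rng = np.random.default_rng(17)
        release = destination_point(home, 90.0, 61.0)
        n = 5 * 360 + 1
        headings = rng.uniform(0, 360, n - 1)
        pts = [release]
        for h in headings:
            pts.append(destination_point(pts[-1], h, 0.1))
        fixes = pd.DataFrame(
            {
                "time": pd.Timestamp(T0) + pd.to_timedelta(np.arange(n) * 10, unit="s"),
                "lat": [p.lat for p in pts],
                "lon": [p.lon for p in pts],
            }
        )
        track = make_track(fixes, release, home)
        maap = mean_aggregate_azimuth_penalty(track)
        samples = [pts[k * 360] for k in range(6)]  # fixes land exactly on boundaries
        devs = []
        for p, q in zip(samples[:-1], samples[1:]):
            A = bearing_deg(p.lat, p.lon, home.lat, home.lon)
            a = bearing_deg(p.lat, p.lon, q.lat, q.lon)
            devs.append(angular_difference(A, a))
        assert maap == pytest.approx(float(np.mean(devs)), abs=1e-9)

    def test_time_shift_invariance(self, home):
        release = destination_point(home, 61.0, 59.9)
        fixes = aimed_track_fixes(release, home, 15.0, 3 * 360 + 1, bearing_offset=30.0)
        t1 = make_track(fixes, release, home)
        shifted = fixes.copy()
        shifted["time"] = shifted["time"] + pd.Timedelta(days=2)
        t2 = make_track(shifted, release, home, t0=pd.Timestamp(T0) + pd.Timedelta(days=2))
        assert mean_aggregate_azimuth_penalty(t1) == pytest.approx(
            mean_aggregate_azimuth_penalty(t2), abs=1e-12
        )

    def test_short_track_raises(self, home):
        release = destination_point(home, 61.0, 59.9)
        fixes = aimed_track_fixes(release, home, 60.0, 30)  # < 1 h span
        with pytest.raises(ValueError, match="fewer than 2 hourly samples"):
            mean_aggregate_azimuth_penalty(make_track(fixes, release, home))


class TestComputeIndices:
    def test_straight_home_track_summary(self, home):
        release = destination_point(home, 61.0, 30.0)
        # ~2 h to home at 15 km/h; widen the active-flight window so the
        # HEI truncation happens at home arrival, not at the 50 min clock
        fixes = aimed_track_fixes(release, home, 15.0, 2 * 360 + 20, stop_at_target=True)
        res = compute_indices(
            make_track(fixes, release, home),
            IndicesConfig(active_minutes=240.0, home_radius_km=0.0),
        )
        assert res.hei == pytest.approx(1.0, abs=1e-6)
        assert res.maap == pytest.approx(0.0, abs=1.0)
        assert res.endpoint_distance_km < 0.6
        assert res.consistent

    def test_due_west_flight_zero_deviation(self, home):
        release = destination_point(home, 90.0, 61.0)
        fixes = straight_track_fixes(release, 270.0, 60.0, 120)
        res = compute_indices(make_track(fixes, release, home))
        assert res.deviation_from_west == pytest.approx(0.0, abs=0.5)

    def test_signed_vs_absolute_convention(self, home):
        release = destination_point(home, 129.0, 50.5)  # home azimuth 309: east of west
        fixes = aimed_track_fixes(release, home, 60.0, 120)
        signed = compute_indices(make_track(fixes, release, home), IndicesConfig(signed_west=True))
        absol = compute_indices(make_track(fixes, release, home), IndicesConfig(signed_west=False))
        assert signed.deviation_from_west == pytest.approx(39.0, abs=1.5)
        assert absol.deviation_from_west == pytest.approx(abs(signed.deviation_from_west), abs=1e-9)

    def test_batch_table(self, home):
        from olfnav.synthetic import gen_track

        release = destination_point(home, 61.0, 59.9)
        tracks = [
            gen_track(release, home, bird_id=f"b{i}", seed=i, max_duration_min=12.0)
            for i in range(10)
        ]
        table = indices_table(tracks)
        assert len(table) == 10
        assert table["bird_id"].is_unique
        assert table["consistent"].all()  # strongly homeward-biased walks orient
        assert (table.loc[table["consistent"], "r"] >= 0.1).all()
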
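"""GPS densification, geofence construction, and per-tree aggregation."""

import numpy as np
import pandas as pd
import pytest

from canopysense.geosync import (
    GeoTrack,
    TreeAnchor,
    aggregate_by_interval,
    build_geofences,
    densify_track,
    ground_distance_m,
    region_intervals,
)
from canopysense.synthetic import METERS_PER_DEG_LAT, gen_transect, pass_time


def _line_track(times, lats, lon=144.95):
    n = len(times)
    return GeoTrack(
        times=np.asarray(times, float),
        lats=np.asarray(lats, float),
        lons=np.full(n, lon),
        alts=np.zeros(n),
    )


class TestDensify:
    def test_linear_midpoint(self):
        track = _line_track([0.0, 1.0], [0.0, 0.0010])
        dense = densify_track(track, 10)
        i = np.argmin(np.abs(dense.times - 0.5))
        assert dense.times[i] == pytest.approx(0.5)
        assert dense.lats[i] == pytest.approx(0.0005)

    def test_inclusive_grid_count(self):
        dense = densify_track(_line_track([0.0, 1.0], [0.0, 0.001]), 10)
        assert len(dense) == 11

    def test_idempotent_on_dense_track(self):
        times = np.arange(0, 2.001, 0.1)
        track = _line_track(times, np.linspace(0, 0.001, len(times)))
        dense = densify_track(track, 10)
        assert len(dense) == len(track)
        np.testing.assert_allclose(dense.lats, track.lats, atol=1e-12)

    def test_endpoints_preserved_for_ragged_span(self):
        track = _line_track([0.0, 1.27], [0.0, 0.001])
        dense = densify_track(track, 10)
        assert dense.times[0] == 0.0 and dense.times[-1] == 1.27
        assert dense.lats[-1] == pytest.approx(0.001)

    def test_non_monotonic_rejected(self):
        with pytest.raises(ValueError):
            _line_track([0.0, 1.0, 0.5], [0, 0, 0])


class TestGeofences:
    def _anchors(self, spacing_m, n=3):
        return [
            TreeAnchor(f"T{i}", -37.79 + i * spacing_m / METERS_PER_DEG_LAT, 144.95)
            for i in range(n)
        ]

    def test_radius_capped(self):
        regions = build_geofences(self._anchors(40.0), max_radius_m=15)
        assert all(r.radius_m == pytest.approx(15, rel=1e-3) for r in regions)

    def test_half_spacing_rule(self):
        regions = build_geofences(self._anchors(20.0), max_radius_m=15)
        assert all(r.radius_m == pytest.approx(10, rel=1e-3) for r in regions)

    def test_single_anchor_gets_max_radius(self):
        regions = build_geofences([TreeAnchor("T1", -37.79, 144.95)])
        assert regions[0].radius_m == 15.0

    def test_duplicate_anchor_rejected(self):
        a = TreeAnchor("T1", -37.79, 144.95)
        b = TreeAnchor("T2", -37.79, 144.95)
        with pytest.raises(ValueError):
            build_geofences([a, b])

    def test_adjacent_regions_disjoint(self):
        regions = build_geofences(self._anchors(18.0, n=5), max_radius_m=15)
        for r1, r2 in zip(regions, regions[1:]):
            d = ground_distance_m(r1.latitude, r1.longitude, r2.latitude, r2.longitude)
            assert r1.radius_m + r2.radius_m <= d + 1e-9


class TestRegionIntervals:
    def test_pass_duration_matches_geometry(self):
        # 10 m radius crossed at 5.6 m/s: chord = 2r on a through-centre pass
        track, anchors = gen_transect(1, speed_mps=5.6, rate_hz=10, lead_m=30)
        regions = build_geofences(anchors, max_radius_m=10)
        dense = densify_track(track, 10)
        ivs = region_intervals(dense, regions)
        assert len(ivs) == 1
        dur = ivs[0].exit_time - ivs[0].entry_time
        assert dur == pytest.approx(20 / 5.6, abs=0.25)

    def test_track_outside_all_regions(self):
        track = _line_track([0.0, 10.0], [-37.0, -37.0], lon=140.0)
        regions = build_geofences([TreeAnchor("T1", -37.79, 144.95)])
        assert region_intervals(densify_track(track, 10), regions) == []

    def test_stationary_inside_spans_whole_track(self):
        a = TreeAnchor("T1", -37.79, 144.95)
        track = _line_track(
            [0.0, 5.0], [-37.79 + 1 / METERS_PER_DEG_LAT] * 2, lon=144.95
        )
        ivs = region_intervals(densify_track(track, 10), build_geofences([a]))
        assert ivs[0].entry_time == 0.0 and ivs[0].exit_time == 5.0

    def test_kinematic_truth_within_grid_step(self):
        n, spacing, v = 20, 30.0, 5.6
        track, anchors = gen_transect(n, spacing_m=spacing, speed_mps=v, rate_hz=1)
        regions = build_geofences(anchors, max_radius_m=15)
        dense = densify_track(track, 10)
        ivs = region_intervals(dense, regions)
        assert len(ivs) == n
        for i, iv in enumerate(sorted(ivs, key=lambda x: x.entry_time)):
            t_pass = pass_time(i, spacing, v)
            r = regions[i].radius_m
            assert abs(iv.entry_time - (t_pass - r / v)) <= 0.1 + 1e-9
            assert abs(iv.exit_time - (t_pass + r / v)) <= 0.1 + 1e-9


class TestAggregation:
    def _setup(self):
        track, anchors = gen_transect(5, rate_hz=1)
        dense = densify_track(track, 10)
        regions = build_geofences(anchors)
        return dense, region_intervals(dense, regions)

    def test_constant_stream(self):
        dense, ivs = self._setup()
        stream = pd.DataFrame({"time": dense.times, "x": 2.5})
        records = aggregate_by_interval(stream, ivs)
        assert len(records) == 5
        assert all(r.means["x"] == 2.5 for r in records)

    def test_three_sample_mean(self):
        from canopysense.geosync import RegionInterval

        stream = pd.DataFrame({"time": [0.0, 1.0, 2.0, 9.0], "x": [1.0, 2.0, 3.0, 99.0]})
        recs = aggregate_by_interval(stream, [RegionInterval("T1", 0.0, 2.0)])
        assert recs[0].means["x"] == pytest.approx(2.0)
        assert recs[0].counts["x"] == 3

    def test_matches_bruteforce_filter(self, rng):
        dense, ivs = self._setup()
        times = np.sort(rng.uniform(dense.times[0], dense.times[-1], 200))
        vals = rng.normal(0, 1, 200)
        stream = pd.DataFrame({"time": times, "x": vals})
        for rec in aggregate_by_interval(stream, ivs):
            windows = [(iv.entry_time, iv.exit_time) for iv in ivs if iv.tree_id == rec.tree_id]
            selected = [
                v for t, v in zip(times, vals)
                if any(lo <= t <= hi for lo, hi in windows)
            ]
            if selected:
                assert rec.means["x"] == pytest.approx(np.mean(selected), rel=1e-12)
                assert rec.counts["x"] == len(selected)
            else:
                assert np.isnan(rec.means["x"]) and rec.counts["x"] == 0

    def test_no_double_assignment_and_conservation(self, rng):
        dense, ivs = self._setup()
        times = np.sort(rng.uniform(dense.times[0], dense.times[-1], 500))
        assigned = np.zeros(len(times), dtype=int)
        for iv in ivs:
            assigned += (times >= iv.entry_time) & (times <= iv.exit_time)
        assert assigned.max() <= 1
        stream = pd.DataFrame({"time": times, "x": 1.0})
        total = sum(r.counts["x"] for r in aggregate_by_interval(stream, ivs))
        assert total <= len(times)

    def test_empty_window_yields_nan_not_zero(self):
        from canopysense.geosync import RegionInterval

        stream = pd.DataFrame({"time": [10.0], "x": [7.0]})
        recs = aggregate_by_interval(stream, [RegionInterval("T1", 0.0, 1.0)])
        assert np.isnan(recs[0].means["x"])
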
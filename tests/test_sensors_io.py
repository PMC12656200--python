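"""E-nose log parsing, SRT sidecars, campaign means, and the weather table."""

import numpy as np
import pytest

from canopysense.geosync import GeoTrack
from canopysense.sensors_io import (
    GAS_CHANNELS,
    CalibrationError,
    SchemaError,
    baseline_adjust,
    bundled_weather_path,
    campaign_means,
    parse_srt,
    read_enose_log,
    read_weather_table,
    write_enose_log,
    write_srt,
)

HEADER = "timestamp,lat,lon,alt,MQ3,MQ4,MQ7,MQ8,MQ135,MQ136,MQ137,MQ138,MG811,temp_C,rh_pct"


def _log(tmp_path, rows):
    path = tmp_path / "run.csv"
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return path


def _row(ts="2021-04-19T05:02:07Z", volts=None, temp=19.2, rh=60.0):
    volts = volts or [1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9]
    v = ",".join(str(x) for x in volts)
    return f"{ts},-37.79,144.95,40.0,{v},{temp},{rh}"


class TestEnoseLog:
    def test_inline_fixture_verbatim(self, tmp_path):
        rows = [
            _row("2021-04-19T05:02:07Z"),
            _row("2021-04-19T05:02:08Z", volts=[0.5] * 9),
            _row("2021-04-19T05:02:09Z"),
        ]
        samples = read_enose_log(_log(tmp_path, rows))
        assert len(samples) == 3
        assert samples[1].voltages["MQ135"] == 0.5
        assert samples[0].voltages["MG811"] == 1.9
        assert samples[0].temperature == 19.2

    def test_out_of_range_flagged_not_dropped(self, tmp_path):
        samples = read_enose_log(
            _log(tmp_path, [_row(volts=[9.9] + [1.0] * 8)])
        )
        assert len(samples) == 1 and samples[0].out_of_range

    def test_one_hz_campaign_count(self, tmp_path):
        rows = [
            _row(f"2021-04-19T05:{m:02d}:{s:02d}Z")
            for m in range(12) for s in range(60)
        ]
        assert len(read_enose_log(_log(tmp_path, rows))) == 720

    def test_missing_channel_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("timestamp,lat,lon,alt,MQ3\n2021-04-19T05:02:07Z,0,0,0,1\n")
        with pytest.raises(SchemaError):
            read_enose_log(path)

    def test_bad_timestamp_row_rejected(self, tmp_path):
        samples = read_enose_log(_log(tmp_path, [_row(ts="not-a-time"), _row()]))
        assert len(samples) == 1

    def test_round_trip_identity(self, tmp_path, rng):
        rows = [
            _row(f"2021-04-19T05:02:{s:02d}Z", volts=list(np.round(rng.uniform(0.2, 4.8, 9), 4)))
            for s in range(5)
        ]
        first = read_enose_log(_log(tmp_path, rows))
        write_enose_log(first, tmp_path / "copy.csv")
        second = read_enose_log(tmp_path / "copy.csv")
        for a, b in zip(first, second):
            assert a.timestamp == pytest.approx(b.timestamp, abs=1e-3)
            assert a.voltages == b.voltages
            assert (a.latitude, a.longitude, a.altitude) == (b.latitude, b.longitude, b.altitude)
            assert (a.temperature, a.humidity) == (b.temperature, b.humidity)


class TestBaselineAdjust:
    def test_constant_channel_zeroed(self, tmp_path):
        rows = [_row(f"2021-04-19T05:02:{s:02d}Z", volts=[1.0] * 9) for s in range(10)]
        samples = read_enose_log(_log(tmp_path, rows))
        adjusted = baseline_adjust(samples, baseline_window_s=5)
        assert all(v == 0.0 for s in adjusted for v in s.voltages.values())

    def test_ramp_minus_baseline_mean(self, tmp_path):
        rows = [
            _row(f"2021-04-19T05:02:{s:02d}Z", volts=[0.1 * s] * 9) for s in range(10)
        ]
        samples = read_enose_log(_log(tmp_path, rows))
        adjusted = baseline_adjust(samples, baseline_window_s=4)
        b = np.mean([0.0, 0.1, 0.2, 0.3])
        for s, orig in zip(adjusted, samples):
            assert s.voltages["MQ3"] == pytest.approx(orig.voltages["MQ3"] - b)

    def test_empty_input_rejected(self):
        with pytest.raises(CalibrationError):
            baseline_adjust([], 60)


class TestCampaignMeans:
    def test_two_sample_mean(self, tmp_path):
        rows = [_row(volts=[1.0] * 9), _row(ts="2021-04-19T05:02:08Z", volts=[3.0] * 9)]
        summary = campaign_means(read_enose_log(_log(tmp_path, rows)), "M1")
        assert all(v == pytest.approx(2.0) for v in summary.means.values())
        assert summary.stacked_total == pytest.approx(18.0)
        assert summary.n_samples == 2

    def test_permutation_invariant(self, tmp_path, rng):
        rows = [
            _row(f"2021-04-19T05:02:{s:02d}Z", volts=list(np.round(rng.uniform(0, 5, 9), 3)))
            for s in range(8)
        ]
        samples = read_enose_log(_log(tmp_path, rows))
        fwd = campaign_means(samples, "M1")
        rev = campaign_means(samples[::-1], "M1")
        assert fwd.means == rev.means

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            campaign_means([], "M1")


class TestSrt:
    def test_round_trip(self, tmp_path):
        track = GeoTrack(
            times=np.array([1_618_801_200.0, 1_618_801_201.0, 1_618_801_202.5]),
            lats=np.array([-37.79, -37.7902, -37.7905]),
            lons=np.array([144.95, 144.9501, 144.9502]),
            alts=np.array([40.0, 40.5, 41.0]),
        )
        write_srt(track, tmp_path / "track.srt")
        back = parse_srt(tmp_path / "track.srt")
        np.testing.assert_allclose(back.times, track.times, atol=1e-3)
        np.testing.assert_allclose(back.lats, track.lats, atol=1e-7)
        np.testing.assert_allclose(back.alts, track.alts, atol=0.1)


class TestWeatherTable:
    def test_fixture_parses_every_cell(self):
        records = {r.date: r for r in read_weather_table(bundled_weather_path())}
        r19 = records["2021-04-19"]
        assert (r19.t_min, r19.t_max, r19.rainfall) == (12.0, 20.6, 0.0)
        assert r19.wind_dir == "NW" and r19.wind_speed_max == 30.0
        assert r19.wind_time_max == "13:27"
        assert (r19.t_9am, r19.rh_9am, r19.wind_dir_9am, r19.ws_9am) == (15.3, 64.0, "N", 9.0)
        assert r19.mslp_9am == 1018.4
        assert (r19.t_3pm, r19.rh_3pm, r19.wind_dir_3pm, r19.ws_3pm) == (18.9, 47.0, "NNW", 15.0)
        assert r19.mslp_3pm == 1014.1
        r21 = records["2021-04-21"]
        assert (r21.t_min, r21.t_max, r21.rainfall, r21.wind_speed_max) == (7.1, 14.9, 10.4, 19.0)
        assert (r21.t_9am, r21.rh_9am, r21.ws_9am, r21.mslp_9am) == (10.0, 65.0, 2.0, 1019.2)
        assert (r21.t_3pm, r21.rh_3pm, r21.wind_dir_3pm, r21.ws_3pm, r21.mslp_3pm) == (
            14.2, 48.0, "S", 7.0, 1015.4,
        )
        r22 = records["2021-04-22"]
        assert (r22.t_min, r22.t_max, r22.wind_dir, r22.wind_speed_max) == (9.9, 17.0, "WSW", 30.0)
        assert (r22.mslp_9am, r22.mslp_3pm) == (1013.3, 1012.0)
        r29 = records["2021-04-29"]
        assert (r29.t_min, r29.t_max, r29.wind_dir, r29.wind_speed_max) == (8.2, 18.4, "SSW", 17.0)
        assert r29.ws_9am == 0.0  # "Calm" cell
        assert r29.wind_dir_9am is None
        assert (r29.rh_9am, r29.mslp_9am, r29.mslp_3pm) == (83.0, 1025.1, 1022.9)

    def test_tmin_above_tmax_rejected(self, tmp_path):
        text = bundled_weather_path().read_text().splitlines()
        bad = text[1].split(",")
        bad[1], bad[2] = "25", "20.6"
        (tmp_path / "w.csv").write_text(text[0] + "\n" + ",".join(bad) + "\n")
        with pytest.raises(ValueError):
            read_weather_table(tmp_path / "w.csv")
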
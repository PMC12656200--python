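"""Readers and writers for E-nose logs, SRT GPS sidecars, and weather tables.

The E-nose is a nine-channel metal-oxide-semiconductor (MOS) gas sensor array
(MQ-3, MQ-4, MQ-7, MQ-8, MQ-135, MQ-136, MQ-137, MQ-138, MG811) plus an
ambient temperature/humidity sensor, logged at 1 Hz to CSV alongside a GPS
fix.  Voltages live on a 5 V rail; out-of-range values are flagged but kept,
since transient spikes should not destroy rows.  The camera writes a SubRip
(.srt) sidecar whose payload lines carry the GPS fix of each video frame.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geosync import GeoTrack

log = logging.getLogger(__name__)

GAS_CHANNELS = ("MQ3", "MQ4", "MQ7", "MQ8", "MQ135", "MQ136", "MQ137", "MQ138", "MG811")
ENOSE_COLUMNS = ("timestamp", "lat", "lon", "alt") + GAS_CHANNELS + ("temp_C", "rh_pct")
VOLTAGE_RANGE = (0.0, 5.0)


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class CalibrationError(ValueError):
    """Baseline window contains no samples."""


@dataclass
class GasSample:
    """One 1 Hz E-nose record: GPS fix, nine voltages, ambient conditions."""

    timestamp: float  # UTC epoch seconds
    latitude: float
    longitude: float
    altitude: float
    voltages: dict[str, float]
    temperature: float
    humidity: float
    out_of_range: bool = False


@dataclass(frozen=True)
class CampaignSummary:
    """Per-channel mean voltages over one measurement campaign."""

    campaign_id: str
    means: dict[str, float]
    stacked_total: float  # sum of channel means, for stacked-bar comparison
    start: float
    end: float
    n_samples: int


@dataclass(frozen=True)
class WeatherRecord:
    """One day of Bureau-of-Meteorology style observations."""

    date: str
    t_min: float
    t_max: float
    rainfall: float
    wind_dir: Optional[str]
    wind_speed_max: float
    wind_time_max: Optional[str]
    t_9am: float
    rh_9am: float
    wind_dir_9am: Optional[str]
    ws_9am: float
    mslp_9am: float
    t_3pm: float
    rh_3pm: float
    wind_dir_3pm: Optional[str]
    ws_3pm: float
    mslp_3pm: float


def _parse_iso(ts: str) -> float:
    s = str(ts).strip().replace("Z", "+00:00")
    dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def _format_iso(epoch: float) -> str:
    dt = datetime.fromtimestamp(epoch, tz=timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"


def read_enose_log(path: str | Path) -> list[GasSample]:
    """Parse an E-nose CSV log into ordered :class:`GasSample` records.

    Rows with unparseable timestamps are rejected (logged); voltages outside
    the 5 V rail flag the sample but keep it.
    """
    df = pd.read_csv(path)
    missing = set(ENOSE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"E-nose log missing columns: {sorted(missing)}")
    samples = []
    for i, row in df.iterrows():
        try:
            ts = _parse_iso(row["timestamp"])
        except (ValueError, TypeError):
            log.warning("row %d rejected: bad timestamp %r", i, row["timestamp"])
            continue
        volts = {ch: float(row[ch]) for ch in GAS_CHANNELS}
        oor = any(not VOLTAGE_RANGE[0] <= v <= VOLTAGE_RANGE[1] for v in volts.values())
        if oor:
            log.warning("row %d flagged: voltage outside %s", i, VOLTAGE_RANGE)
        samples.append(
            GasSample(
                timestamp=ts,
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                altitude=float(row["alt"]),
                voltages=volts,
                temperature=float(row["temp_C"]),
                humidity=float(row["rh_pct"]),
                out_of_range=oor,
            )
        )
    return samples


def write_enose_log(samples: Sequence[GasSample], path: str | Path) -> None:
    """Write samples back to the canonical E-nose CSV schema."""
    rows = []
    for s in samples:
        row = {
            "timestamp": _format_iso(s.timestamp),
            "lat": s.latitude,
            "lon": s.longitude,
            "alt": s.altitude,
        }
        row.update({ch: s.voltages[ch] for ch in GAS_CHANNELS})
        row["temp_C"] = s.temperature
        row["rh_pct"] = s.humidity
        rows.append(row)
    pd.DataFrame(rows, columns=list(ENOSE_COLUMNS)).to_csv(path, index=False)


def enose_frame(samples: Sequence[GasSample]) -> pd.DataFrame:
    """Samples as a DataFrame with a ``time`` column, ready for aggregation."""
    rows = []
    for s in samples:
        row = {"time": s.timestamp}
        row.update({ch: s.voltages[ch] for ch in GAS_CHANNELS})
        row["temp_C"] = s.temperature
        row["rh_pct"] = s.humidity
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_adjust(
    samples: Sequence[GasSample], baseline_window_s: float
) -> list[GasSample]:
    """Subtract the mean of the opening baseline window from every channel.

    The instrument records clean-air baselines before each campaign; this
    hook removes them.  It is *not* applied by default anywhere in the
    pipeline, which analyses raw voltages.
    """
    if not samples:
        raise CalibrationError("no samples")
    t0 = samples[0].timestamp
    window = [s for s in samples if s.timestamp < t0 + baseline_window_s]
    if not window:
        raise CalibrationError("empty baseline window")
    base = {
        ch: float(np.mean([s.voltages[ch] for s in window])) for ch in GAS_CHANNELS
    }
    out = []
    for s in samples:
        out.append(
            GasSample(
                timestamp=s.timestamp,
                latitude=s.latitude,
                longitude=s.longitude,
                altitude=s.altitude,
                voltages={ch: s.voltages[ch] - base[ch] for ch in GAS_CHANNELS},
                temperature=s.temperature,
                humidity=s.humidity,
                out_of_range=s.out_of_range,
            )
        )
    return out


def campaign_means(
    samples: Sequence[GasSample], campaign_id: str
) -> CampaignSummary:
    """Arithmetic per-channel mean voltage over one campaign."""
    if not samples:
        raise ValueError("no samples in campaign")
    means = {
        ch: float(np.mean([s.voltages[ch] for s in samples])) for ch in GAS_CHANNELS
    }
    return CampaignSummary(
        campaign_id=campaign_id,
        means=means,
        stacked_total=float(sum(means.values())),
        start=min(s.timestamp for s in samples),
        end=max(s.timestamp for s in samples),
        n_samples=len(samples),
    )


# --- SRT GPS sidecars -------------------------------------------------------

_SRT_PAYLOAD = re.compile(
    r"^\s*(?P<ts>[\dT:.+Z\- ]+?)\s*,\s*(?P<lat>-?[\d.]+)\s*,\s*"
    r"(?P<lon>-?[\d.]+)\s*,\s*(?P<alt>-?[\d.]+)\s*$"
)


def parse_srt(path: str | Path) -> GeoTrack:
    """Parse a SubRip sidecar whose payload is ``iso-time, lat, lon, alt``."""
    text = Path(path).read_text()
    times, lats, lons, alts = [], [], [], []
    for block in re.split(r"\n\s*\n", text.strip()):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if len(lines) < 3:
            continue
        m = _SRT_PAYLOAD.match(lines[2])
        if not m:
            log.warning("unparseable SRT payload: %r", lines[2])
            continue
        times.append(_parse_iso(m["ts"]))
        lats.append(float(m["lat"]))
        lons.append(float(m["lon"]))
        alts.append(float(m["alt"]))
    return GeoTrack(
        times=np.array(times), lats=np.array(lats), lons=np.array(lons), alts=np.array(alts)
    )


def write_srt(track: GeoTrack, path: str | Path, frame_duration_s: float = 1 / 30) -> None:
    """Write a track as SubRip blocks (one block per frame)."""

    def clock(rel: float) -> str:
        ms = int(round(rel * 1000))
        h, rem = divmod(ms, 3_600_000)
        m, rem = divmod(rem, 60_000)
        s, ms = divmod(rem, 1000)
        return f"{h:02d}:{m:02d}:{s:02d},{ms:03d}"

    t0 = track.times[0]
    blocks = []
    for i in range(len(track)):
        rel = track.times[i] - t0
        payload = (
            f"{_format_iso(track.times[i])},{track.lats[i]:.7f},"
            f"{track.lons[i]:.7f},{track.alts[i]:.1f}"
        )
        blocks.append(
            f"{i + 1}\n{clock(rel)} --> {clock(rel + frame_duration_s)}\n{payload}\n"
        )
    Path(path).write_text("\n".join(blocks))


# --- weather table ----------------------------------------------------------

WEATHER_COLUMNS = (
    "date", "t_min", "t_max", "rainfall", "wind_dir", "wind_speed_max",
    "wind_time_max", "t_9am", "rh_9am", "wind_dir_9am", "ws_9am", "mslp_9am",
    "t_3pm", "rh_3pm", "wind_dir_3pm", "ws_3pm", "mslp_3pm",
)
_SPEED_FIELDS = ("wind_speed_max", "ws_9am", "ws_3pm")
_DIR_FIELDS = ("wind_dir", "wind_dir_9am", "wind_dir_3pm")


def _parse_speed(value) -> float:
    """Wind speed cell; the token ``Calm`` (or a blank) means 0 km/h."""
    s = str(value).strip()
    if s.lower() in ("calm", "", "nan"):
        return 0.0
    return float(s)


def read_weather_table(path: str | Path) -> list[WeatherRecord]:
    """Parse a daily weather CSV into typed records.

    Wind directions may be blank (missing); a ``Calm`` speed parses to 0.
    Days with t_min > t_max are rejected as a validation error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"weather table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {"date": row["date"].strip()}
        for f in ("t_min", "t_max", "rainfall", "t_9am", "rh_9am", "mslp_9am",
                  "t_3pm", "rh_3pm", "mslp_3pm"):
            kwargs[f] = float(row[f])
        for f in _SPEED_FIELDS:
            kwargs[f] = _parse_speed(row[f])
        for f in _DIR_FIELDS:
            v = row[f].strip()
            kwargs[f] = v if v else None
        v = row["wind_time_max"].strip()
        kwargs["wind_time_max"] = v if v else None
        if kwargs["t_min"] > kwargs["t_max"]:
            raise ValueError(f"{kwargs['date']}: t_min > t_max")
        if kwargs["rainfall"] < 0:
            raise ValueError(f"{kwargs['date']}: negative rainfall")
        records.append(WeatherRecord(**kwargs))
    return records


def bundled_weather_path() -> Path:
    """Path of the packaged April-2021 Melbourne daily weather table."""
    return Path(__file__).parent / "data" / "weather_april2021.csv"
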
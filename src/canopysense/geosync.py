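"""GPS densification, per-tree geofencing, and sensor-stream aggregation.

The vehicle logs sparse GPS fixes; these are linearly interpolated onto a
uniform 10 Hz grid.  Around each surveyed tree a circular geofence is built
whose radius is capped and shrunk to half the distance to the neighbouring
trees, so adjacent regions never overlap and no sample can be attributed to
two trees.  Entry/exit timestamps of the vehicle in each region clip every
sensor stream (camera indices, E-nose channels) to per-tree windows, whose
means form the fused per-tree record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8
DEFAULT_RATE_HZ = 10.0
DEFAULT_MAX_RADIUS_M = 15.0


@dataclass(frozen=True)
class GeoTrack:
    """Time-ordered GPS samples; times are UTC epoch seconds."""

    times: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    alts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        la = np.asarray(self.lats, dtype=float)
        lo = np.asarray(self.lons, dtype=float)
        al = np.asarray(self.alts, dtype=float)
        if not (t.shape == la.shape == lo.shape == al.shape):
            raise ValueError("track arrays must share one shape")
        if t.size >= 2 and not (np.diff(t) > 0).all():
            raise ValueError("track timestamps must be strictly increasing")
        if (np.abs(la) > 90).any() or (np.abs(lo) > 180).any():
            raise ValueError("coordinates out of range")
        for name, arr in (("times", t), ("lats", la), ("lons", lo), ("alts", al)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TreeAnchor:
    tree_id: str
    latitude: float
    longitude: float


@dataclass(frozen=True)
class GeofenceRegion:
    tree_id: str
    latitude: float
    longitude: float
    radius_m: float


@dataclass(frozen=True)
class RegionInterval:
    """One contiguous pass of the vehicle through a tree's geofence."""

    tree_id: str
    entry_time: float
    exit_time: float


@dataclass
class TreeRecord:
    """Fused per-tree means over all intervals of that tree."""

    tree_id: str
    entry_time: float
    exit_time: float
    means: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def ground_distance_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Equirectangular ground distance, adequate for sub-10 km extents."""
    lat1, lon1 = np.radians(lat1), np.radians(lon1)
    lat2, lon2 = np.radians(lat2), np.radians(lon2)
    x = (lon2 - lon1) * np.cos(0.5 * (lat1 + lat2))
    y = lat2 - lat1
    return EARTH_RADIUS_M * np.hypot(x, y)


def densify_track(track: GeoTrack, rate_hz: float = DEFAULT_RATE_HZ) -> GeoTrack:
    """Resample a track onto a uniform 1/rate grid, endpoints preserved.

    Coordinates and altitude are linearly interpolated per axis.  If the
    span is not an exact multiple of the step, the final input timestamp is
    appended so that the endpoints survive exactly.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 samples to densify")
    t0, t1 = track.times[0], track.times[-1]
    n_steps = int(math.floor((t1 - t0) * rate_hz + 1e-9))
    grid = t0 + np.arange(n_steps + 1) / rate_hz
    if t1 - grid[-1] > 1e-9:
        grid = np.append(grid, t1)
    return GeoTrack(
        times=grid,
        lats=np.interp(grid, track.times, track.lats),
        lons=np.interp(grid, track.times, track.lons),
        alts=np.interp(grid, track.times, track.alts),
    )


def build_geofences(
    anchors: Sequence[TreeAnchor], max_radius_m: float = DEFAULT_MAX_RADIUS_M
) -> list[GeofenceRegion]:
    """Circular geofences with radii capped at half the inter-anchor spacing.

    Anchors must be ordered along the transect.  Each radius is
    ``min(max_radius_m, d_prev/2, d_next/2)`` so neighbouring regions are
    disjoint by construction.
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    n = len(anchors)
    gaps = [
        float(
            ground_distance_m(
                anchors[i].latitude,
                anchors[i].longitude,
                anchors[i + 1].latitude,
                anchors[i + 1].longitude,
            )
        )
        for i in range(n - 1)
    ]
    if any(g == 0.0 for g in gaps):
        raise ValueError("duplicate anchor coordinates (zero spacing)")
    regions = []
    for i, a in enumerate(anchors):
        radius = max_radius_m
        if i > 0:
            radius = min(radius, gaps[i - 1] / 2)
        if i < n - 1:
            radius = min(radius, gaps[i] / 2)
        regions.append(
            GeofenceRegion(
                tree_id=a.tree_id,
                latitude=a.latitude,
                longitude=a.longitude,
                radius_m=radius,
            )
        )
    return regions


def region_intervals(
    dense: GeoTrack, regions: Sequence[GeofenceRegion]
) -> list[RegionInterval]:
    """Entry/exit timestamps of every contiguous pass through each region.

    Entry is the first grid timestamp whose ground distance to the centre is
    within the radius; exit is the last timestamp of the same contiguous run.
    A tree that is never entered is simply absent (logged).  Out-and-back
    transects therefore yield multiple intervals per tree.
    """
    out: list[RegionInterval] = []
    for region in regions:
        d = ground_distance_m(dense.lats, dense.lons, region.latitude, region.longitude)
        inside = d <= region.radius_m
        if not inside.any():
            log.info("tree %s never entered", region.tree_id)
            continue
        padded = np.concatenate(([False], inside, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):
            out.append(
                RegionInterval(
                    tree_id=region.tree_id,
                    entry_time=float(dense.times[start]),
                    exit_time=float(dense.times[stop - 1]),
                )
            )
    out.sort(key=lambda iv: iv.entry_time)
    return out


def aggregate_by_interval(
    stream: pd.DataFrame,
    intervals: Sequence[RegionInterval],
    time_col: str = "time",
) -> list[TreeRecord]:
    """Mean each stream parameter over every tree's geofence windows.

    ``stream`` must carry a sorted ``time_col`` column plus numeric parameter
    columns.  A sample belongs to a tree when ``entry <= t <= exit`` for any
    of that tree's intervals; multiple passes are pooled into a single mean.
    Trees whose windows contain no samples get NaN means and zero counts.
    """
    times = stream[time_col].to_numpy(dtype=float)
    if times.size and (np.diff(times) < 0).any():
        raise ValueError("stream timestamps must be sorted")
    params = [c for c in stream.columns if c != time_col]
    by_tree: dict[str, list[RegionInterval]] = {}
    for iv in intervals:
        by_tree.setdefault(iv.tree_id, []).append(iv)
    records = []
    for tree_id, ivs in by_tree.items():
        sel = np.zeros(times.shape, dtype=bool)
        for iv in ivs:
            sel |= (times >= iv.entry_time) & (times <= iv.exit_time)
        rec = TreeRecord(
            tree_id=tree_id,
            entry_time=min(iv.entry_time for iv in ivs),
            exit_time=max(iv.exit_time for iv in ivs),
        )
        sub = stream.loc[sel, params]
        for p in params:
            vals = pd.to_numeric(sub[p], errors="coerce")
            n = int(vals.notna().sum())
            rec.counts[p] = n
            rec.means[p] = float(vals.mean()) if n else float("nan")
        if not sel.any():
            log.info("tree %s: no stream samples in its windows", tree_id)
        records.append(rec)
    records.sort(key=lambda r: r.entry_time)
    return records


def records_to_frame(records: Iterable[TreeRecord]) -> pd.DataFrame:
    """Flatten tree records into a table (one row per tree)."""
    rows = []
    for r in records:
        row = {"tree_id": r.tree_id, "entry_time": r.entry_time, "exit_time": r.exit_time}
        row.update(r.means)
        row.update({f"n_{k}": v for k, v in r.counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def read_anchors_csv(path: str | Path) -> list[TreeAnchor]:
    """Anchors CSV with columns tree_id, latitude, longitude."""
    df = pd.read_csv(path)
    required = {"tree_id", "latitude", "longitude"}
    if not required <= set(df.columns):
        raise ValueError(f"anchors CSV must have columns {sorted(required)}")
    if df["tree_id"].duplicated().any():
        raise ValueError("tree_id values must be unique")
    return [
        TreeAnchor(str(r.tree_id), float(r.latitude), float(r.longitude))
        for r in df.itertuples()
    ]
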
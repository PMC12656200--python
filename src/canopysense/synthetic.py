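"""Ground-truthed synthetic fixtures for every pipeline stage.

Generators emulate the field inputs — upward RGB canopy frames, radiometric
thermal frames, a vehicle transect with tree anchors, 1 Hz gas-sensor logs,
and gas-to-physiology linked datasets — with their ground truth recorded, so
recovery can be asserted without any field recording.

The canopy scene generator composes foliage from jittered elliptical blobs
with circular holes punched for within-crown porosity, arranged per grid
cell so the realised crown cover and porosity land close to their targets.
Realised cover values are obtained by running the package's own gap analysis
on the noise-free foliage mask; the rendered RGB frame adds per-pixel colour
noise, so the imaging pipeline must genuinely recover the mask through
histogram thresholding.  Sky and canopy blue levels (220 vs 60) sit far
apart, with Gaussian colour noise (sd 10) keeping valley detection
non-trivial.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .geosync import GeoTrack, TreeAnchor
from .imaging_rgb import (
    DEFAULT_GRID,
    DEFAULT_K,
    DEFAULT_LARGE_GAP_FRACTION,
    SkyCanopyMask,
    analytic_lai,
    cover_metrics,
    grid_gap_counts,
    _grid_edges,
)
from .imaging_thermal import ThermalFrame

SKY_RGB = (150, 170, 220)
CANOPY_RGB = (50, 110, 60)
COLOR_NOISE_SD = 10.0
MAX_FC_TARGET = 0.98
# keep cell sky fractions clear of the large-gap cutoff so the plan is stable
LG_MARGIN = 0.03
CANOPY_CELL_SKY_CAP = DEFAULT_LARGE_GAP_FRACTION - 0.05


class GeneratorError(ValueError):
    """The requested scene targets are unreachable."""


@dataclass
class SceneTruth:
    """Generator bookkeeping for one canopy scene."""

    fc_target: float
    phi_target: float
    ff: float  # realised foliage cover on the noise-free mask
    fc: float  # realised crown cover (grid gap analysis of the truth mask)
    phi: float  # realised crown porosity
    seed: int
    foliage_mask: np.ndarray = None  # True where foliage

    @property
    def lai_analytic(self) -> float:
        return analytic_lai(self.fc, self.phi, DEFAULT_K)


@dataclass
class LinkedDatasetTruth:
    """Coefficients of the latent-state -> gas-voltage generator."""

    coefficients: dict
    noise_sd: float
    n: int
    seed: int
    t_wet: float
    t_dry: float


def _plan_large_gap_cells(
    cells: list[tuple[int, int, int, int]],
    fc_target: float,
    rng: np.random.Generator,
    lg_frac: float,
) -> dict[int, float]:
    """Assign cells to be large gaps, with per-cell sky fractions.

    Returns {cell index: sky fraction}, where every fraction sits safely
    above the large-gap cutoff.  Greedy pixel accounting keeps the realised
    crown cover within ~0.02 of the target.
    """
    npx = [
        (r1 - r0) * (c1 - c0) for (r0, r1, c0, c1) in cells
    ]
    total = float(sum(npx))
    remaining = (1.0 - fc_target) * total
    s_min = lg_frac + LG_MARGIN
    order = rng.permutation(len(cells))
    plan: dict[int, float] = {}
    for idx in order:
        if remaining <= 0:
            break
        cell_px = npx[idx]
        if remaining >= s_min * cell_px:
            s = min(1.0, remaining / cell_px)
            plan[int(idx)] = s
            remaining -= s * cell_px
        else:
            # under half a minimum cell left: skipping beats overshooting
            if remaining > 0.5 * s_min * cell_px:
                plan[int(idx)] = s_min
                remaining = 0.0
            break
    return plan


def _cell_blobs(
    sub: np.ndarray, target_canopy: int, rng: np.random.Generator
) -> None:
    """Grow foliage in a cell with jittered elliptical blobs (in place)."""
    h, w = sub.shape
    guard = 0
    while sub.sum() < target_canopy and guard < 500:
        guard += 1
        deficit = target_canopy - int(sub.sum())
        r_mean = math.sqrt(deficit / math.pi)
        ry = min(max(2.0, r_mean * rng.uniform(0.6, 1.3)), 0.45 * h)
        rx = min(max(2.0, r_mean * rng.uniform(0.6, 1.3)), 0.45 * w)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rr, cc = draw_ellipse(
            cy, cx, ry, rx, shape=(h, w), rotation=rng.uniform(0, math.pi)
        )
        sub[rr, cc] = True


def _cell_trim(
    sub: np.ndarray, target_sky: int, rng: np.random.Generator, tol: int
) -> None:
    """Adjust a cell's sky count toward the target with small disks (in place).

    Punches circular holes in foliage when sky is short, or adds foliage
    disks when sky is in excess; half-sized disks make convergence geometric.
    """
    h, w = sub.shape
    guard = 0
    while guard < 1000:
        guard += 1
        sky = sub.size - int(sub.sum())
        d = sky - target_sky
        if abs(d) <= tol:
            return
        radius = min(max(2.0, 0.5 * math.sqrt(abs(d) / math.pi)), min(h, w) / 4)
        want_state = d > 0  # too much sky -> paint foliage onto a sky pixel
        candidates = np.flatnonzero(sub.ravel() != want_state)
        if candidates.size == 0:
            return
        pick = int(candidates[rng.integers(candidates.size)])
        cy, cx = divmod(pick, w)
        rr, cc = draw_disk((cy, cx), radius, shape=(h, w))
        sub[rr, cc] = want_state


def gen_canopy_scene(
    fc_target: float,
    phi_target: float,
    width: int = 512,
    height: int = 512,
    seed: int = 0,
    grid_rows: int = DEFAULT_GRID[0],
    grid_cols: int = DEFAULT_GRID[1],
    large_gap_fraction: float = DEFAULT_LARGE_GAP_FRACTION,
) -> tuple[np.ndarray, SceneTruth]:
    """Render an upward canopy RGB frame with known cover and porosity.

    Some grid cells become pure (or nearly pure) sky — the between-crown
    large gaps — while the rest are filled with elliptical foliage blobs and
    punched with circular holes until their within-cell sky fraction matches
    the requested porosity.  Realised ff/fc/phi are measured by running the
    gap analysis on the final noise-free mask and recorded in the truth.
    """
    if not (0.0 <= fc_target <= MAX_FC_TARGET):
        raise GeneratorError(f"fc_target must be in [0, {MAX_FC_TARGET}]")
    if not (0.0 <= phi_target < 1.0):
        raise GeneratorError("phi_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    foliage = np.zeros((height, width), dtype=bool)

    if fc_target > 0.0:
        cells = [
            (r0, r1, c0, c1)
            for r0, r1 in _grid_edges(height, grid_rows)
            for c0, c1 in _grid_edges(width, grid_cols)
        ]
        lg_plan = _plan_large_gap_cells(cells, fc_target, rng, large_gap_fraction)
        lg_sky_px = sum(
            s * (cells[i][1] - cells[i][0]) * (cells[i][3] - cells[i][2])
            for i, s in lg_plan.items()
        )
        total = float(height * width)
        fc_plan = 1.0 - lg_sky_px / total
        ff_plan = fc_plan * (1.0 - phi_target)
        canopy_cells = [i for i in range(len(cells)) if i not in lg_plan]
        canopy_px = sum(
            (cells[i][1] - cells[i][0]) * (cells[i][3] - cells[i][2])
            for i in canopy_cells
        )
        # sky still owed once large-gap cells are accounted for
        canopy_sky = max(0.0, (1.0 - ff_plan) * total - lg_sky_px)
        s_canopy = min(canopy_sky / canopy_px, CANOPY_CELL_SKY_CAP) if canopy_px else 0.0

        for i, (r0, r1, c0, c1) in enumerate(cells):
            sub = foliage[r0:r1, c0:c1]
            npx = sub.size
            if i in lg_plan:
                target_sky = int(round(lg_plan[i] * npx))
            else:
                target_sky = int(round(s_canopy * npx))
                _cell_blobs(sub, npx - target_sky, rng)
            tol = max(8, npx // 1500)
            _cell_trim(sub, target_sky, rng, tol)

    gc = grid_gap_counts(
        SkyCanopyMask(labels=~foliage, threshold_used=-1),
        grid_rows, grid_cols, large_gap_fraction,
    )
    cm = cover_metrics(gc)
    truth = SceneTruth(
        fc_target=fc_target, phi_target=phi_target,
        ff=cm.ff, fc=cm.fc, phi=cm.phi, seed=seed, foliage_mask=foliage,
    )

    rgb = np.empty((height, width, 3), dtype=float)
    for ch in range(3):
        rgb[..., ch] = np.where(foliage, CANOPY_RGB[ch], SKY_RGB[ch])
    rgb += rng.normal(0.0, COLOR_NOISE_SD, rgb.shape)
    return np.clip(rgb, 0, 255).astype(np.uint8), truth


def gen_thermal_scene(
    canopy_mask: np.ndarray,
    t_sky: float = -30.0,
    t_canopy_mean: float = 20.0,
    t_canopy_sd: float = 2.0,
    seed: int = 0,
    timestamp: Optional[float] = None,
    frame_id: str = "synthetic",
) -> ThermalFrame:
    """Thermal frame over a known canopy mask: cold sky, warm noisy foliage."""
    mask = np.asarray(canopy_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    temps = np.full(mask.shape, t_sky, dtype=float)
    temps += rng.normal(0.0, 0.5, mask.shape)
    if t_canopy_sd > 0:
        canopy = rng.normal(t_canopy_mean, t_canopy_sd, mask.shape)
    else:
        canopy = np.full(mask.shape, t_canopy_mean)
    temps[mask] = canopy[mask]
    return ThermalFrame(temperatures=temps, timestamp=timestamp, frame_id=frame_id)


METERS_PER_DEG_LAT = 6_371_008.8 * math.pi / 180.0


def gen_transect(
    n_trees: int,
    spacing_m: float = 30.0,
    speed_mps: float = 5.6,
    rate_hz: float = 1.0,
    jitter_m: float = 0.0,
    seed: int = 0,
    lat0: float = -37.79,
    lon0: float = 144.955,
    lead_m: float = 20.0,
    t0: float = 0.0,
) -> tuple[GeoTrack, list[TreeAnchor]]:
    """Collinear tree anchors plus a constant-speed drive-past GPS track.

    The transect runs due north; the vehicle starts ``lead_m`` before the
    first tree and finishes the same distance past the last, so tree ``i`` is
    passed at t0 + (lead_m + i*spacing_m)/speed.  Optional GPS jitter is
    zero-mean Gaussian in metres.
    """
    if n_trees < 1:
        raise ValueError("need at least one tree")
    rng = np.random.default_rng(seed)
    anchors = [
        TreeAnchor(
            tree_id=f"T{i + 1:03d}",
            latitude=lat0 + i * spacing_m / METERS_PER_DEG_LAT,
            longitude=lon0,
        )
        for i in range(n_trees)
    ]
    length = 2 * lead_m + (n_trees - 1) * spacing_m
    duration = length / speed_mps
    n = int(math.floor(duration * rate_hz)) + 1
    times = t0 + np.arange(n) / rate_hz
    dist = (times - t0) * speed_mps - lead_m  # metres past the first tree
    lats = lat0 + dist / METERS_PER_DEG_LAT
    lons = np.full(n, lon0)
    if jitter_m > 0:
        lats = lats + rng.normal(0, jitter_m, n) / METERS_PER_DEG_LAT
        lon_scale = METERS_PER_DEG_LAT * math.cos(math.radians(lat0))
        lons = lons + rng.normal(0, jitter_m, n) / lon_scale
    alts = np.full(n, 40.0)
    return GeoTrack(times=times, lats=lats, lons=lons, alts=alts), anchors


def pass_time(
    tree_index: int, spacing_m: float = 30.0, speed_mps: float = 5.6,
    lead_m: float = 20.0, t0: float = 0.0,
) -> float:
    """Kinematic truth: instant the vehicle is abreast of a given tree."""
    return t0 + (lead_m + tree_index * spacing_m) / speed_mps


_SHAPES = {
    "linear": lambda u: u,
    "sqrt": np.sqrt,
    "square": lambda u: u**2,
}


def gen_linked_dataset(
    n: int, noise_sd: float = 0.05, seed: int = 0
) -> tuple["pd.DataFrame", "pd.DataFrame", LinkedDatasetTruth]:
    """Per-tree gas readings linked to physiology by a smooth latent model.

    Each tree draws a latent state (LAI in [0.3, 4.8], water-stress level in
    [0.35, 0.95], ambient temperature and humidity).  The physiological
    targets follow the thermal-index relations with fixed references
    (T_wet = 15, T_dry = 30 degC): TWSI equals the stress level, Ig is its
    conductance-index counterpart, CTD is canopy minus ambient temperature.
    Each gas channel is a seeded smooth monotone function of the latent state
    plus Gaussian voltage noise, mirroring the field observation that sensor
    responses rise with leaf area and fall with stomatal conductance.
    """
    import pandas as pd

    if n < 50:
        raise ValueError("need n >= 50")
    rng = np.random.default_rng(seed)
    lai = rng.uniform(0.3, 4.8, n)
    stress = rng.uniform(0.35, 0.95, n)  # becomes TWSI
    t_wet, t_dry = 15.0, 30.0
    t_canopy = t_wet + stress * (t_dry - t_wet)
    t_ambient = rng.uniform(16.0, 24.0, n)
    humidity = rng.uniform(30.0, 80.0, n)
    ig = np.clip((t_dry - t_canopy) / (t_canopy - t_wet), 0.0, 10.0)
    ctd = t_canopy - t_ambient

    u = lai / 4.8
    v = stress
    channels = ("MQ3", "MQ4", "MQ7", "MQ8", "MQ135", "MQ136", "MQ137", "MQ138", "MG811")
    shape_names = list(_SHAPES)
    coeffs: dict[str, dict] = {}
    volts: dict[str, np.ndarray] = {}
    for ch in channels:
        c = {
            "base": float(rng.uniform(0.4, 0.9)),
            "b_lai": float(rng.uniform(0.4, 0.9)),
            "b_stress": float(rng.uniform(0.4, 0.9)) * float(rng.choice([-1.0, 1.0])),
            "shape_lai": shape_names[int(rng.integers(3))],
            "shape_stress": shape_names[int(rng.integers(3))],
        }
        coeffs[ch] = c
        signal = (
            c["base"]
            + c["b_lai"] * _SHAPES[c["shape_lai"]](u)
            + c["b_stress"] * _SHAPES[c["shape_stress"]](v)
        )
        volts[ch] = np.clip(signal + rng.normal(0, noise_sd, n) + 1.0, 0.05, 4.95)

    features = pd.DataFrame(volts)
    features["temp_C"] = t_ambient + rng.normal(0, 2 * noise_sd, n)
    features["rh_pct"] = humidity + rng.normal(0, 10 * noise_sd, n)
    features.insert(0, "tree_id", [f"T{i + 1:04d}" for i in range(n)])
    targets = pd.DataFrame({"twsi": stress, "ig": ig, "ctd": ctd, "lai": lai})
    truth = LinkedDatasetTruth(
        coefficients=coeffs, noise_sd=noise_sd, n=n, seed=seed,
        t_wet=t_wet, t_dry=t_dry,
    )
    return features, targets, truth


def write_campaign(
    out_dir,
    n_trees: int = 5,
    seed: int = 0,
    frame_size: int = 200,
    spacing_m: float = 30.0,
    speed_mps: float = 5.6,
    fc_range: tuple[float, float] = (0.4, 0.8),
    phi_range: tuple[float, float] = (0.15, 0.4),
    t_canopy_mean: float = 20.0,
) -> dict:
    """Write a full synthetic campaign to disk in the formats the readers consume.

    Produces ``frames/`` (one RGB PNG per tree at its pass time), ``thermal/``
    (float32 degC TIFF per tree), matching ``frames.srt``/``thermal.srt``
    sidecars, a 1 Hz ``enose.csv``, ``anchors.csv`` and ``weather.csv``.
    Returns the per-tree ground truth (realised cover, analytic LAI).
    """
    import shutil
    from pathlib import Path

    import pandas as pd
    import tifffile
    from PIL import Image

    from .sensors_io import (
        GAS_CHANNELS,
        bundled_weather_path,
        write_srt,
    )

    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    (out_dir / "thermal").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    t0 = 1_618_801_200.0  # an April 2021 morning, UTC epoch seconds

    track, anchors = gen_transect(
        n_trees, spacing_m=spacing_m, speed_mps=speed_mps, rate_hz=1.0,
        seed=seed, t0=t0,
    )
    pd.DataFrame(
        {
            "tree_id": [a.tree_id for a in anchors],
            "latitude": [a.latitude for a in anchors],
            "longitude": [a.longitude for a in anchors],
        }
    ).to_csv(out_dir / "anchors.csv", index=False)

    truth: dict[str, dict] = {}
    frame_times, frame_lats, frame_lons = [], [], []
    for i, anchor in enumerate(anchors):
        fc_t = float(rng.uniform(*fc_range))
        phi_t = float(rng.uniform(*phi_range))
        scene_seed = int(rng.integers(2**31 - 1))
        rgb, scene = gen_canopy_scene(
            fc_t, phi_t, width=frame_size, height=frame_size, seed=scene_seed
        )
        t_pass = pass_time(i, spacing_m, speed_mps, t0=t0)
        Image.fromarray(rgb).save(out_dir / "frames" / f"frame_{i:04d}.png")
        thermal = gen_thermal_scene(
            scene.foliage_mask, t_canopy_mean=t_canopy_mean,
            seed=scene_seed + 1, timestamp=t_pass,
        )
        tifffile.imwrite(
            out_dir / "thermal" / f"frame_{i:04d}.tif",
            thermal.temperatures.astype(np.float32),
        )
        frame_times.append(t_pass)
        frame_lats.append(anchor.latitude)
        frame_lons.append(anchor.longitude)
        truth[anchor.tree_id] = {
            "fc": scene.fc,
            "phi": scene.phi,
            "ff": scene.ff,
            "lai_analytic": scene.lai_analytic,
            "pass_time": t_pass,
        }

    frame_track = GeoTrack(
        times=np.array(frame_times),
        lats=np.array(frame_lats),
        lons=np.array(frame_lons),
        alts=np.full(len(frame_times), 40.0),
    )
    write_srt(frame_track, out_dir / "frames.srt")
    write_srt(frame_track, out_dir / "thermal.srt")
    write_srt(track, out_dir / "track.srt", frame_duration_s=1.0)

    rows = []
    for j in range(len(track)):
        row = {
            "timestamp": track.times[j],
            "lat": track.lats[j],
            "lon": track.lons[j],
            "alt": track.alts[j],
        }
        for k, ch in enumerate(GAS_CHANNELS):
            row[ch] = float(
                1.0 + 0.3 * k / 9 + 0.2 * math.sin(2 * math.pi * j / 60 + k)
                + rng.normal(0, 0.02)
            )
        row["temp_C"] = float(t_canopy_mean + rng.normal(0, 0.3))
        row["rh_pct"] = float(55.0 + rng.normal(0, 1.0))
        rows.append(row)
    df = pd.DataFrame(rows)
    from datetime import datetime, timezone

    df["timestamp"] = [
        datetime.fromtimestamp(t, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"
        for t in df["timestamp"]
    ]
    df.to_csv(out_dir / "enose.csv", index=False)
    shutil.copy(bundled_weather_path(), out_dir / "weather.csv")
    return truth
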
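"""Radiometric thermal frames: canopy segmentation and water-stress indices.

An upward-facing radiometric camera sees foliage near air temperature and
clear sky far below 0 degC, so a temperature cutoff separates canopy from sky.
From the canopy pixel distribution two reference temperatures are taken as
percentiles: T_wet (fully transpiring leaf, cool extreme) and T_dry
(non-transpiring leaf, warm extreme).  The indices are

    raw stress index = (T_canopy - T_wet) / (T_dry - T_wet)   (CWSI form)
    TWSI = raw index clipped to [0, 1]
    Ig   = (T_dry - T_canopy) / (T_canopy - T_wet)            (conductance index)
    CTD  = T_canopy - T_average                               (depression vs air)

where T_average is ambient air temperature from the co-mounted environmental
sensors.  Higher stress raises the raw index and lowers Ig; CTD is negative
when transpiration cools the canopy below the air.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_SKY_CUTOFF = 0.0  # degC
DEFAULT_P_WET = 5.0
DEFAULT_P_DRY = 95.0
DEFAULT_IG_MAX = 10.0
MIN_CANOPY_PIXELS = 20


class EmptyCanopyError(ValueError):
    """No pixel in the frame is above the sky cutoff; the frame is skipped."""


class DegenerateReferenceError(ValueError):
    """Wet and dry reference temperatures coincide."""


@dataclass(frozen=True)
class ThermalFrame:
    """One radiometric frame in degC, with optional acquisition metadata."""

    temperatures: np.ndarray
    timestamp: Optional[float] = None  # UTC epoch seconds
    emissivity: float = 0.98
    frame_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size == 0:
            raise ValueError("empty thermal frame")
        if not np.isfinite(t).all():
            raise ValueError("thermal frame contains non-finite temperatures")
        if t.min() < -80.0 or t.max() > 80.0:
            raise ValueError("temperatures outside the plausible [-80, 80] degC range")
        object.__setattr__(self, "temperatures", t)


@dataclass(frozen=True)
class WaterStatus:
    """Stress indices for one frame (or one tree)."""

    t_canopy: float
    t_wet: float
    t_dry: float
    raw_index: float  # unbounded CWSI-form value
    twsi: float  # raw index clipped to [0, 1]
    ig: float
    ctd: float
    t_average: float


def canopy_mask_thermal(
    frame: ThermalFrame, sky_cutoff: float = DEFAULT_SKY_CUTOFF
) -> np.ndarray:
    """Boolean mask of canopy pixels: temperature strictly above ``sky_cutoff``.

    Sky radiance seen from below maps to strongly negative apparent
    temperatures, while foliage tracks air temperature, so pixels above the
    cutoff are foliage.  Raises :class:`EmptyCanopyError` when nothing
    clears the cutoff.
    """
    mask = frame.temperatures > sky_cutoff
    if not mask.any():
        raise EmptyCanopyError(
            f"no pixel above {sky_cutoff} degC in frame {frame.frame_id!r}"
        )
    return mask


def reference_temperatures(
    canopy_temps: Sequence[float] | np.ndarray,
    p_wet: float = DEFAULT_P_WET,
    p_dry: float = DEFAULT_P_DRY,
) -> tuple[float, float]:
    """Wet/dry reference temperatures as percentiles of the canopy pixels.

    Linear interpolation between order statistics; requires at least
    20 canopy pixels and a non-degenerate temperature spread.
    """
    temps = np.asarray(canopy_temps, dtype=float).ravel()
    if temps.size < MIN_CANOPY_PIXELS:
        raise ValueError(
            f"need >= {MIN_CANOPY_PIXELS} canopy pixels, got {temps.size}"
        )
    t_wet, t_dry = np.percentile(temps, [p_wet, p_dry], method="linear")
    if not t_wet < t_dry:
        raise DegenerateReferenceError(
            "degenerate canopy temperature distribution: T_wet == T_dry"
        )
    return float(t_wet), float(t_dry)


def compute_stress_indices(
    t_canopy: float,
    t_wet: float,
    t_dry: float,
    t_average: float,
    ig_max: float = DEFAULT_IG_MAX,
) -> WaterStatus:
    """Raw stress index, TWSI, Ig and CTD from canopy/reference temperatures."""
    if not t_wet < t_dry:
        raise DegenerateReferenceError("require T_wet < T_dry")
    raw = (t_canopy - t_wet) / (t_dry - t_wet)
    twsi = min(max(raw, 0.0), 1.0)
    if t_canopy > t_wet:
        ig = (t_dry - t_canopy) / (t_canopy - t_wet)
        ig = min(max(ig, 0.0), ig_max)
    else:
        ig = ig_max
    return WaterStatus(
        t_canopy=float(t_canopy),
        t_wet=float(t_wet),
        t_dry=float(t_dry),
        raw_index=float(raw),
        twsi=float(twsi),
        ig=float(ig),
        ctd=float(t_canopy - t_average),
        t_average=float(t_average),
    )


def water_status_for_frame(
    frame: ThermalFrame,
    t_average: float,
    sky_cutoff: float = DEFAULT_SKY_CUTOFF,
    p_wet: float = DEFAULT_P_WET,
    p_dry: float = DEFAULT_P_DRY,
    ig_max: float = DEFAULT_IG_MAX,
) -> WaterStatus:
    """Full single-frame chain: mask, canopy mean, references, indices."""
    mask = canopy_mask_thermal(frame, sky_cutoff)
    canopy = frame.temperatures[mask]
    t_canopy = float(canopy.mean())
    t_wet, t_dry = reference_temperatures(canopy, p_wet, p_dry)
    return compute_stress_indices(t_canopy, t_wet, t_dry, t_average, ig_max)


def summarize_campaign(values) -> "pd.DataFrame":
    """Min/max/mean/SD per metric over the frames of one campaign.

    ``values`` is a DataFrame (or dict of sequences) with one row per frame.
    SD uses the n-1 denominator, returning 0 for a single frame.
    """
    import pandas as pd

    df = pd.DataFrame(values)
    if len(df) == 0:
        raise ValueError("no frames to summarize")
    num = df.select_dtypes("number")
    sd = num.std(ddof=1).fillna(0.0)
    return pd.DataFrame(
        {"min": num.min(), "max": num.max(), "mean": num.mean(), "sd": sd}
    )


@dataclass(frozen=True)
class ThermalCalibration:
    """Linear count-to-degC conversion for raw radiometric TIFF counts."""

    gain: float = 1.0
    offset: float = 0.0

    def apply(self, counts: np.ndarray) -> np.ndarray:
        return np.asarray(counts, dtype=float) * self.gain + self.offset


def read_thermal_frames(
    path: str | Path,
    calibration: ThermalCalibration = ThermalCalibration(),
    timestamps: Optional[Sequence[float]] = None,
) -> list[ThermalFrame]:
    """Read thermal frames from a TIFF directory, multi-page TIFF, or matrix file.

    TIFF pixel values are passed through the linear calibration; ``.csv`` /
    ``.txt`` files are read as plain degC matrices.  Frames are ordered
    lexicographically for directories.
    """
    import tifffile

    path = Path(path)
    arrays: list[np.ndarray] = []
    ids: list[str] = []
    if path.is_dir():
        for p in sorted(path.iterdir()):
            if p.suffix.lower() in (".tif", ".tiff"):
                arrays.append(calibration.apply(tifffile.imread(p)))
                ids.append(p.stem)
            elif p.suffix.lower() in (".csv", ".txt"):
                arrays.append(np.loadtxt(p, delimiter=","))
                ids.append(p.stem)
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        stack = stack[None] if stack.ndim == 2 else stack
        for i, page in enumerate(stack):
            arrays.append(calibration.apply(page))
            ids.append(f"{path.stem}_{i:05d}")
    else:
        arrays.append(np.loadtxt(path, delimiter=","))
        ids.append(path.stem)
    frames = []
    for i, (arr, fid) in enumerate(zip(arrays, ids)):
        ts = None if timestamps is None else float(timestamps[i])
        frames.append(ThermalFrame(temperatures=arr, timestamp=ts, frame_id=fid))
    return frames
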
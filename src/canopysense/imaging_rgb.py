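"""Upward-looking RGB canopy photography: cover fractions and leaf area index.

A single frame shot from below a street tree contains two pixel populations,
bright sky and dark foliage, which separate cleanly in the blue channel.  The
processing chain is:

1. blue-channel histogram, thresholded at the valley between the sky and
   canopy peaks (automated here; a manual threshold can be supplied);
2. binarisation into a sky/canopy mask;
3. gap analysis on a 5x5 grid of sub-images, where a sub-image that is at
   least 75 % sky is classed a *large gap* (a between-crown gap rather than a
   within-crown one);
4. cover fractions and Beer-Lambert inversion to leaf area index:

   f_f = 1 - (all gap pixels)/(all pixels)          foliage cover
   f_c = 1 - (large-gap pixels)/(all pixels)        crown cover
   phi = 1 - f_f/f_c                                crown porosity
   LAI  = -f_c * ln(phi) / k                        (k = 0.5 extinction)
   Omega(0) = (1-phi) * ln(1-f_f) / (ln(phi) * f_f) zenith clumping index
   LAIe = LAI * Omega(0)                            effective LAI
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}

#: extinction coefficient of a spherical leaf-angle distribution
DEFAULT_K = 0.5
#: a sub-image is a "large gap" when at least this fraction of it is sky
DEFAULT_LARGE_GAP_FRACTION = 0.75
DEFAULT_GRID = (5, 5)


class BimodalityError(ValueError):
    """Histogram is not bimodal; an automatic threshold cannot be chosen."""


@dataclass(frozen=True)
class Histogram256:
    """Per-intensity pixel tally for one 8-bit channel."""

    counts: np.ndarray  # shape (256,), non-negative ints
    channel: str

    def __post_init__(self) -> None:
        if self.counts.shape != (256,):
            raise ValueError("histogram must have 256 bins")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")


@dataclass(frozen=True)
class SkyCanopyMask:
    """Binary labelling of a frame; ``labels`` is True where a pixel is sky."""

    labels: np.ndarray  # bool, same height x width as the source frame
    threshold_used: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class GapCounts:
    """Pixel tallies from the grid gap analysis of one mask."""

    total_pixels: int
    gap_pixels_total: int
    large_gap_pixels: int
    grid_rows: int
    grid_cols: int
    large_gap_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.large_gap_pixels <= self.gap_pixels_total <= self.total_pixels):
            raise ValueError(
                "inconsistent tallies: need large_gap <= gap_total <= total"
            )


@dataclass(frozen=True)
class CoverMetrics:
    """Cover fractions and leaf area indices derived from :class:`GapCounts`."""

    ff: float
    fc: float
    phi: float
    omega0: float
    lai: float
    laie: float
    k: float = DEFAULT_K


def _as_rgb_array(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ValueError(f"expected an HxWx3 RGB frame, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError("expected 8-bit channels (uint8)")
    return frame


def channel_histogram(frame: np.ndarray, channel: str = "blue") -> Histogram256:
    """Tally one colour channel of an 8-bit RGB frame into 256 bins."""
    frame = _as_rgb_array(frame)
    try:
        idx = CHANNEL_INDEX[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None
    counts = np.bincount(frame[..., idx].ravel(), minlength=256)
    return Histogram256(counts=counts, channel=channel)


def detect_valley_threshold(
    hist: Histogram256,
    smoothing_window: int = 11,
    min_peak_separation: int = 30,
) -> int:
    """Locate the valley between the two dominant histogram peaks.

    Peaks are detected on a moving-average-smoothed copy of the histogram
    (window ``smoothing_window`` bins, minimum separation
    ``min_peak_separation`` bins); the threshold is the lowest raw count
    strictly between the two tallest peaks, ties broken to the lowest
    intensity.  Raises :class:`BimodalityError` when fewer than two peaks
    survive smoothing, in which case a manual threshold must be supplied.
    """
    counts = hist.counts.astype(float)
    kernel = np.ones(smoothing_window) / smoothing_window
    smooth = np.convolve(counts, kernel, mode="same")
    peaks, _ = find_peaks(smooth, distance=min_peak_separation)
    if len(peaks) < 2:
        raise BimodalityError(
            "histogram is not bimodal after smoothing; "
            "supply a manual threshold instead"
        )
    top_two = peaks[np.argsort(smooth[peaks])][-2:]
    lo, hi = int(top_two.min()), int(top_two.max())
    interior = counts[lo + 1 : hi]
    if interior.size == 0:
        raise BimodalityError("peaks are adjacent; no valley exists between them")
    return lo + 1 + int(np.argmin(interior))


def binarize_sky_canopy(frame: np.ndarray, threshold: int) -> SkyCanopyMask:
    """Label a pixel *sky* iff its blue value is strictly above ``threshold``."""
    frame = _as_rgb_array(frame)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    labels = frame[..., CHANNEL_INDEX["blue"]] > threshold
    return SkyCanopyMask(labels=labels, threshold_used=int(threshold))


def _grid_edges(n: int, cells: int) -> list[tuple[int, int]]:
    """Cell bounds along one axis; remainder pixels merge into the last cell."""
    base = n // cells
    edges = [(i * base, (i + 1) * base) for i in range(cells)]
    edges[-1] = (edges[-1][0], n)
    return edges


def grid_gap_counts(
    mask: SkyCanopyMask,
    grid_rows: int = DEFAULT_GRID[0],
    grid_cols: int = DEFAULT_GRID[1],
    large_gap_fraction: float = DEFAULT_LARGE_GAP_FRACTION,
) -> GapCounts:
    """Tally gap pixels on a ``grid_rows`` x ``grid_cols`` sub-image grid.

    A sub-image whose sky proportion is >= ``large_gap_fraction`` is classed
    a large gap and contributes its sky pixels to ``large_gap_pixels``.
    """
    labels = mask.labels
    h, w = labels.shape
    if h < grid_rows or w < grid_cols:
        raise ValueError(
            f"mask {h}x{w} smaller than the {grid_rows}x{grid_cols} grid"
        )
    large = 0
    for r0, r1 in _grid_edges(h, grid_rows):
        for c0, c1 in _grid_edges(w, grid_cols):
            cell = labels[r0:r1, c0:c1]
            sky = int(cell.sum())
            if sky >= large_gap_fraction * cell.size:
                large += sky
    return GapCounts(
        total_pixels=labels.size,
        gap_pixels_total=int(labels.sum()),
        large_gap_pixels=large,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        large_gap_fraction=large_gap_fraction,
    )


def cover_metrics(
    gc: GapCounts, k: float = DEFAULT_K, phi_floor: float = 1e-4
) -> CoverMetrics:
    """Convert gap tallies to cover fractions, porosity, clumping and LAI.

    ``phi`` is clamped to ``[phi_floor, 1 - phi_floor]`` so that a fully
    closed (or fully porous) crown yields a large-but-finite LAI instead of a
    logarithmic singularity.  A frame with no crown cover returns zero LAI.
    """
    if gc.total_pixels == 0:
        raise ValueError("GapCounts with zero total pixels")
    total = float(gc.total_pixels)
    ff = 1.0 - gc.gap_pixels_total / total
    fc = 1.0 - gc.large_gap_pixels / total
    if fc <= 0.0:
        # open sky: no crowns, hence no leaf area
        return CoverMetrics(ff=ff, fc=fc, phi=1.0, omega0=1.0, lai=0.0, laie=0.0, k=k)
    phi = min(max(1.0 - ff / fc, phi_floor), 1.0 - phi_floor)
    lai = -fc * math.log(phi) / k
    if ff <= 0.0:
        # limit of ln(1-ff)/ff as ff -> 0 is -1
        omega0 = (1.0 - phi) / (-math.log(phi))
    else:
        ff_eff = min(ff, 1.0 - 1e-12)
        omega0 = (1.0 - phi) * math.log1p(-ff_eff) / (math.log(phi) * ff)
    return CoverMetrics(ff=ff, fc=fc, phi=phi, omega0=omega0, lai=lai, laie=lai * omega0, k=k)


def analytic_lai(fc: float, phi: float, k: float = DEFAULT_K) -> float:
    """Closed-form Beer-Lambert LAI for known crown cover and porosity."""
    if fc <= 0.0 or phi <= 0.0:
        return 0.0
    return -fc * math.log(phi) / k


def process_frame(
    frame: np.ndarray,
    threshold: Optional[int] = None,
    grid_rows: int = DEFAULT_GRID[0],
    grid_cols: int = DEFAULT_GRID[1],
    large_gap_fraction: float = DEFAULT_LARGE_GAP_FRACTION,
    k: float = DEFAULT_K,
) -> tuple[int, CoverMetrics]:
    """Full single-frame chain: histogram -> threshold -> mask -> metrics."""
    if threshold is None:
        threshold = detect_valley_threshold(channel_histogram(frame, "blue"))
    mask = binarize_sky_canopy(frame, threshold)
    gc = grid_gap_counts(mask, grid_rows, grid_cols, large_gap_fraction)
    return threshold, cover_metrics(gc, k=k)


def process_directory(
    frames_dir: str | Path,
    threshold: Optional[int] = None,
    grid_rows: int = DEFAULT_GRID[0],
    grid_cols: int = DEFAULT_GRID[1],
    large_gap_fraction: float = DEFAULT_LARGE_GAP_FRACTION,
    k: float = DEFAULT_K,
):
    """Process every image in a directory (lexicographic order).

    Returns a :class:`pandas.DataFrame` with one row per frame:
    frame_id, threshold, ff, fc, phi, omega0, lai, laie.
    """
    import pandas as pd

    frames_dir = Path(frames_dir)
    patterns = (".png", ".jpg", ".jpeg", ".tif", ".tiff")
    paths = sorted(p for p in frames_dir.iterdir() if p.suffix.lower() in patterns)
    rows = []
    for path in paths:
        frame = np.asarray(Image.open(path).convert("RGB"))
        try:
            thr, cm = process_frame(
                frame, threshold, grid_rows, grid_cols, large_gap_fraction, k
            )
        except BimodalityError:
            log.warning("skipping %s: histogram not bimodal", path.name)
            continue
        rows.append(
            {
                "frame_id": path.stem,
                "threshold": thr,
                "ff": cm.ff,
                "fc": cm.fc,
                "phi": cm.phi,
                "omega0": cm.omega0,
                "lai": cm.lai,
                "laie": cm.laie,
            }
        )
    return pd.DataFrame(rows)
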
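"""Center decoding, shifted-set detection and repair, and crop geometry.

The center detector can mis-assign channels when the body above L1 (T12)
is mistaken for L1: every channel then locks onto the vertebra one above
its true target down to some level j, leaving one true center with no
channel.  The signature of this failure is one inter-maximum gap about
twice the normal spacing.  Detection uses the gap statistic: with
``d_i = ||max(C_i) - max(C_{i+1})||_2`` for the 5 consecutive pairs, the
set is flagged when ``max(d) > 1.4 * mean(d excluding its maximum)``.

Repair recovers the missing center from the *sum* of all channels, where
the missed vertebra still produces a secondary (low-confidence) blob:
every row outside the central band of the suspicious gap is zeroed
(keeping y in ``[y_j + 0.4 d_max, y_{j+1} - 0.4 d_max]`` with d_max the
y-distance of the flanking maxima), the surviving argmax becomes the new
center, the topmost original maximum (the T12 intruder) is dropped, and
the new point is inserted between positions j and j+1.

Crop side lengths derive from neighboring center y-distances: 1.5x the
single adjacent gap at the ends, 0.75x the sum of both gaps in the middle,
and the sacrum reuses the L4-L5 gap because the L5-S1 distance is too
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .prep import FrameTransform, gaussian_blur

__all__ = [
    "GapStats",
    "CropSpec",
    "extract_maxima",
    "gap_check",
    "repair_centers",
    "crop_sizes",
    "crop_vertebra",
]

GAP_FACTOR = 1.4
BAND_FACTOR = 0.4


@dataclass
class GapStats:
    """Per-channel maxima, consecutive gaps, and the 1.4-rule verdict.

    ``j`` is the 1-based index of the largest gap (between maxima j and
    j+1); ``mean_rest`` excludes exactly one occurrence of that maximum.
    """

    maxima: np.ndarray
    d: np.ndarray
    j: int
    mean_rest: float
    flagged: bool


@dataclass
class CropSpec:
    """A square crop window: center point and side length in the source frame."""

    center: tuple[float, float]
    side: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.side > 0:
            raise ValueError("crop side must be positive")


def extract_maxima(stack: np.ndarray) -> np.ndarray:
    """Per-channel global argmax as (x, y); row-major first-occurrence ties.

    A constant channel has no informative peak; its centroid is used and a
    warning emitted.
    """
    maps = np.asarray(stack, dtype=np.float64)
    if maps.ndim != 3:
        raise ValueError("expected a K x H x W stack")
    h, w = maps.shape[1:]
    pts = np.empty((maps.shape[0], 2), dtype=float)
    for k, ch in enumerate(maps):
        if np.ptp(ch) == 0:
            warnings.warn(f"constant center channel {k}: falling back to centroid")
            pts[k] = ((w - 1) / 2.0, (h - 1) / 2.0)
            continue
        idx = int(np.argmax(ch))
        pts[k] = (idx % w, idx // w)
    return pts


def gap_check(maxima: np.ndarray) -> GapStats:
    """Evaluate the shifted-set gap statistic on 6 channel maxima."""
    pts = np.asarray(maxima, dtype=float)
    if pts.shape != (6, 2):
        raise ValueError("expected 6 ordered center maxima")
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    jm = int(np.argmax(d))
    rest = np.delete(d, jm)
    mean_rest = float(rest.mean())
    flagged = bool(d[jm] > GAP_FACTOR * mean_rest)
    return GapStats(maxima=pts, d=d, j=jm + 1, mean_rest=mean_rest, flagged=flagged)


def repair_centers(stack: np.ndarray, gap: GapStats) -> tuple[np.ndarray, bool]:
    """Recover the missing center of a flagged shifted set.

    Returns ``(6 ordered points, repaired)``.  Only the upward-shift mode
    (a spurious top point) is defined; if the masked channel sum carries no
    signal the original maxima are returned with ``repaired=False`` and a
    warning.
    """
    if not gap.flagged:
        raise ValueError("repair_centers requires a flagged gap statistic")
    maps = np.asarray(stack, dtype=np.float64)
    csum = maps.sum(axis=0)
    j = gap.j  # 1-based: gap between maxima j and j+1
    y_hi = gap.maxima[j - 1, 1]
    y_lo = gap.maxima[j, 1]
    dmax = abs(y_lo - y_hi)
    ys = np.arange(csum.shape[0], dtype=float)
    keep = (ys >= y_hi + BAND_FACTOR * dmax) & (ys <= y_lo - BAND_FACTOR * dmax)
    masked = np.where(keep[:, None], csum, 0.0)
    if not masked.any():
        warnings.warn("repair abandoned: masked channel sum is identically zero")
        return gap.maxima.copy(), False
    idx = int(np.argmax(masked))
    w = csum.shape[1]
    max_new = np.array([idx % w, idx // w], dtype=float)
    repaired = np.vstack(
        [gap.maxima[1:j], max_new[None, :], gap.maxima[j:]]
    )
    return repaired, True


def crop_sizes(centers: np.ndarray) -> np.ndarray:
    """Square side length per vertebra from neighboring center y-gaps."""
    pts = np.asarray(centers, dtype=float)
    if pts.shape != (6, 2):
        raise ValueError("expected 6 ordered centers (L1..L5, S1)")
    y = pts[:, 1]
    gaps = np.abs(np.diff(y))
    if np.any(gaps == 0):
        raise ValueError("coincident neighbor y-coordinates give a zero crop side")
    sides = np.empty(6)
    sides[0] = 1.5 * gaps[0]
    for i in (1, 2, 3):
        sides[i] = 0.75 * (gaps[i - 1] + gaps[i])
    sides[4] = 1.5 * gaps[3]
    sides[5] = 1.5 * gaps[3]  # L5-S1 spacing is too variable; reuse L4-L5
    return sides


def crop_vertebra(
    padded_image: np.ndarray,
    spec: CropSpec,
    out_size: int = 256,
    blur_sigma: float = 1.0,
    source_frame: str = "input",
) -> tuple[np.ndarray, FrameTransform]:
    """Extract a square window, resize to ``out_size``, blur; with transform.

    The window is centered on ``spec.center``; parts outside the raster are
    zero-filled.  The returned transform maps crop coordinates back to the
    source frame.
    """
    img = np.asarray(padded_image, dtype=np.float64)
    h, w = img.shape
    cx, cy = spec.center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"crop center ({cx}, {cy}) outside the raster")
    s = spec.side
    scale = s / out_size
    # crop pixel i samples source coordinate x0 + i * scale, so the crop's
    # middle pixel (out_size/2) sits exactly on the window center
    x0, y0 = cx - s / 2.0, cy - s / 2.0
    us = x0 + np.arange(out_size) * scale
    vs = y0 + np.arange(out_size) * scale
    uu, vv = np.meshgrid(us, vs)
    crop = ndimage.map_coordinates(img, [vv, uu], order=1, mode="constant", cval=0.0)
    if blur_sigma > 0:
        crop = gaussian_blur(crop, blur_sigma)
    t = FrameTransform(scale, (x0, y0), "crop", source_frame)
    return crop, t
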
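"""Ground-truth confidence maps and part affinity fields.

Center and corner landmarks are supervised with un-normalized Gaussian
heatmaps, ``C(x) = exp(-||x - c||^2 / (2 sigma^2))``, one channel per
keypoint, peak value exactly 1 at the annotated pixel.  The spread sigma is
tied to anatomy rather than fixed:

* vertebra centers (64x64 frame): half the vertical extent of L5;
* lumbar corners (256x256 crop frame): 1/10 of the mean diagonal of the
  vertebra's four corners;
* sacrum end-plate points (256x256): 1/6 of the end-plate length.

The part affinity field here is a scalar indicator raster marking the upper
and lower end-plate segments (or the single sacrum plate): 1 on a band of
the configured width around each segment, 0 elsewhere.  Both end plates of
a lumbar vertebra share one PAF channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfidenceMapStack",
    "Segment",
    "PafMap",
    "sigma_for",
    "gaussian_map",
    "paf_map",
    "lumbar_segments",
    "sacrum_segment",
]

DEFAULT_PAF_WIDTH = 4.0


@dataclass
class ConfidenceMapStack:
    """K x H x W stack of per-keypoint confidence maps in one frame."""

    maps: np.ndarray
    frame: str
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.maps.ndim != 3:
            raise ValueError("maps must be K x H x W")
        if len(self.channel_labels) != self.maps.shape[0]:
            raise ValueError("one label per channel required")


@dataclass(frozen=True)
class Segment:
    """An end-plate segment between two landmarks."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    kind: str = "top"

    def __post_init__(self) -> None:
        if np.allclose(self.p0, self.p1):
            raise ValueError("segment endpoints must be distinct")


@dataclass
class PafMap:
    map: np.ndarray
    width: float


def sigma_for(kind: str, points: np.ndarray) -> float:
    """Target-map sigma from annotation geometry, in the map's own frame.

    ``points`` are the relevant landmarks already expressed in the frame of
    the map being built: L5's 4 corners for ``"center"`` (heatmap frame),
    the vertebra's 4 corners for ``"lumbar"``, the 2 plate endpoints for
    ``"sacrum"``.
    """
    pts = np.asarray(points, dtype=float)
    if kind == "center":
        if pts.shape != (4, 2):
            raise ValueError("center sigma needs L5's 4 corner points")
        height = pts[:, 1].max() - pts[:, 1].min()
        if height <= 0:
            raise ValueError("degenerate L5 geometry: zero height")
        return 0.5 * height
    if kind == "lumbar":
        if pts.shape != (4, 2):
            raise ValueError("lumbar sigma needs 4 corner points")
        d1 = np.linalg.norm(pts[0] - pts[3])  # Lt <-> Rb
        d2 = np.linalg.norm(pts[1] - pts[2])  # Rt <-> Lb
        if d1 <= 0 or d2 <= 0:
            raise ValueError("degenerate vertebra: zero diagonal")
        return 0.5 * (d1 + d2) / 10.0
    if kind == "sacrum":
        if pts.shape != (2, 2):
            raise ValueError("sacrum sigma needs 2 plate endpoints")
        d = np.linalg.norm(pts[0] - pts[1])
        if d <= 0:
            raise ValueError("degenerate sacrum: zero plate length")
        return d / 6.0
    raise ValueError(f"unknown keypoint kind {kind!r}")


def gaussian_map(
    points: np.ndarray,
    sigma: float,
    shape: tuple[int, int],
    frame: str = "heatmap",
    channel_labels: tuple[str, ...] | None = None,
) -> ConfidenceMapStack:
    """One Gaussian channel per point, peak exactly 1 at the annotated pixel.

    Each annotation is snapped to its nearest pixel center so the channel
    maximum is exactly 1; the sub-pixel remainder is below the argmax decode
    resolution.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h, w = shape
    for x, y in pts:
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"point ({x}, {y}) outside {h}x{w} raster")
    ys, xs = np.mgrid[0:h, 0:w]
    maps = np.empty((len(pts), h, w), dtype=np.float64)
    for k, (x, y) in enumerate(np.round(pts)):
        d2 = (xs - x) ** 2 + (ys - y) ** 2
        maps[k] = np.exp(-d2 / (2.0 * sigma**2))
    if channel_labels is None:
        channel_labels = tuple(f"k{k}" for k in range(len(pts)))
    return ConfidenceMapStack(maps=maps, frame=frame, channel_labels=channel_labels)


def paf_map(segments, width: float, shape: tuple[int, int]) -> PafMap:
    """Indicator raster of the union of segment bands.

    A pixel is 1 iff its center's perpendicular offset from some segment
    lies in [-width/2, width/2) (signed by the segment's left normal) and
    its projection onto the segment falls within the span, endpoints
    inclusive.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    h, w = shape
    out = np.zeros((h, w), dtype=np.float64)
    if not segments:
        return PafMap(map=out, width=width)
    ys, xs = np.mgrid[0:h, 0:w]
    for seg in segments:
        p0 = np.asarray(seg.p0, dtype=float)
        p1 = np.asarray(seg.p1, dtype=float)
        d = p1 - p0
        length2 = float(d @ d)
        tx, ty = xs - p0[0], ys - p0[1]
        t = (tx * d[0] + ty * d[1]) / length2
        perp = (ty * d[0] - tx * d[1]) / np.sqrt(length2)  # signed offset
        band = (perp >= -width / 2) & (perp < width / 2) & (t >= 0) & (t <= 1)
        out[band] = 1.0
    return PafMap(map=out, width=width)


def lumbar_segments(corners: np.ndarray) -> list[Segment]:
    """Top and bottom end-plate segments from (Lt, Rt, Lb, Rb) corners."""
    c = np.asarray(corners, dtype=float)
    return [
        Segment(tuple(c[0]), tuple(c[1]), kind="top"),
        Segment(tuple(c[2]), tuple(c[3]), kind="bottom"),
    ]


def sacrum_segment(plate: np.ndarray) -> list[Segment]:
    p = np.asarray(plate, dtype=float)
    return [Segment(tuple(p[0]), tuple(p[1]), kind="sacrum")]
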
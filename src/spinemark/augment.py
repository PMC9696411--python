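"""Training-time augmentation with annotation-consistent transforms.

The signature augmentation is *random spine cutout* (RSC): instead of
erasing an arbitrary rectangle (conventional cutout), RSC zeroes a
rectangle sized 60% of one randomly chosen upper lumbar vertebra's box
(L1..L4 — the bodies most often shadowed on real radiographs), placed
uniformly inside that box.  This teaches the center detector to localize a
vertebra from its neighbors when the body itself is invisible.

Photometric jitter (brightness/contrast) and geometric jitter (rotation,
uniform scale, translation) warp pixels and annotations with the same
similarity so ground truth stays consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import AnnotatedImage, LUMBAR_LABELS

__all__ = [
    "AugmentConfig",
    "random_spine_cutout",
    "conventional_cutout",
    "photometric_geometric",
]


@dataclass(frozen=True)
class AugmentConfig:
    rsc_ratio: float = 0.6
    rsc_candidates: tuple[str, ...] = ("L1", "L2", "L3", "L4")
    rsc_prob: float = 0.5
    cutout_size: tuple[int, int] = (50, 29)  # (width, height) in px, ~RSC-sized
    brightness_range: tuple[float, float] = (-20.0, 20.0)
    contrast_range: tuple[float, float] = (0.85, 1.15)
    rotation_sd: float = 3.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    translation_range: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.rsc_ratio <= 1:
            raise ValueError("rsc_ratio must be in (0, 1]")
        bad = set(self.rsc_candidates) - set(LUMBAR_LABELS)
        if bad:
            raise ValueError(f"rsc candidates must be lumbar labels, got {bad}")
        if not self.rsc_candidates:
            raise ValueError("rsc candidate set must be nonempty")


def random_spine_cutout(
    sample: AnnotatedImage, cfg: AugmentConfig, rng: np.random.Generator
) -> AnnotatedImage:
    """Zero a ratio-sized rectangle fully inside one random candidate vertebra.

    Annotations are unchanged: the whole point is that the ground truth
    still marks the erased body.
    """
    out = sample.copy()
    label = cfg.rsc_candidates[rng.integers(0, len(cfg.rsc_candidates))]
    x0, y0, x1, y1 = sample.vertebra_boxes[label]
    bw, bh = x1 - x0, y1 - y0
    mw, mh = cfg.rsc_ratio * bw, cfg.rsc_ratio * bh
    ox = x0 + rng.uniform(0, bw - mw)
    oy = y0 + rng.uniform(0, bh - mh)
    c0, c1 = int(round(ox)), int(round(ox + mw))
    r0, r1 = int(round(oy)), int(round(oy + mh))
    h, w = out.pixels.shape
    out.pixels[max(0, r0) : min(h, r1), max(0, c0) : min(w, c1)] = 0.0
    return out


def conventional_cutout(
    sample: AnnotatedImage, cfg: AugmentConfig, rng: np.random.Generator
) -> AnnotatedImage:
    """Zero a fixed-size rectangle uniformly positioned anywhere in the raster."""
    out = sample.copy()
    h, w = out.pixels.shape
    mw, mh = cfg.cutout_size
    if mw > w or mh > h:
        raise ValueError(f"cutout {mw}x{mh} larger than raster {w}x{h}")
    c0 = int(rng.integers(0, w - mw + 1))
    r0 = int(rng.integers(0, h - mh + 1))
    out.pixels[r0 : r0 + mh, c0 : c0 + mw] = 0.0
    return out


def photometric_geometric(
    sample: AnnotatedImage, cfg: AugmentConfig, rng: np.random.Generator
) -> AnnotatedImage:
    """Brightness/contrast jitter plus a random similarity warp.

    The similarity (rotation about the image center, uniform scale,
    translation) is applied identically to pixels and annotation points, so
    annotations track the warped geometry.  Pixels are resampled with
    reflection padding.
    """
    out = sample.copy()

    gain = rng.uniform(*cfg.contrast_range)
    bias = rng.uniform(*cfg.brightness_range)
    out.pixels = np.clip(gain * (out.pixels - 127.5) + 127.5 + bias, 0.0, 255.0)

    theta = np.deg2rad(rng.normal(0, 1) * cfg.rotation_sd)
    s = rng.uniform(*cfg.scale_range)
    tx = rng.uniform(-cfg.translation_range, cfg.translation_range)
    ty = rng.uniform(-cfg.translation_range, cfg.translation_range)

    h, w = out.pixels.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rot = s * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    center = np.array([cx, cy])
    shift = np.array([tx, ty])

    def fwd(pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - center) @ rot.T + center + shift

    # affine_transform pulls output pixels from input via the inverse map,
    # in (row, col) order.
    inv = np.linalg.inv(rot)
    matrix_rc = inv[::-1, ::-1]  # (x,y) inverse expressed on (row, col)
    offset_xy = center - inv @ (center + shift)
    out.pixels = ndimage.affine_transform(
        out.pixels,
        matrix_rc,
        offset=offset_xy[::-1],
        order=1,
        mode="reflect",
    )

    out.centers = fwd(out.centers)
    out.landmarks = {k: fwd(v) for k, v in out.landmarks.items()}
    out.vertebra_boxes = {
        k: (
            float(out.landmarks[k][:, 0].min()),
            float(out.landmarks[k][:, 1].min()),
            float(out.landmarks[k][:, 0].max()),
            float(out.landmarks[k][:, 1].max()),
        )
        for k in out.landmarks
    }
    hh, ww = out.pixels.shape
    all_pts = np.vstack([out.centers] + list(out.landmarks.values()))
    if (
        (all_pts[:, 0] < 0).all()
        or (all_pts[:, 0] > ww - 1).all()
        or (all_pts[:, 1] < 0).all()
        or (all_pts[:, 1] > hh - 1).all()
    ):
        raise ValueError("geometric jitter pushed all annotations outside the raster")
    return out
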
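"""Image preprocessing and coordinate-frame bookkeeping.

The pipeline moves points between four frames: the original raster, the
zero-padded/resized network input (512x512), the center heatmap (64x64,
exactly 1/8 of the input), and per-vertebra crops (256x256).  All of these
are related by similarity maps with uniform scale and translation only, so a
frame transform is a (scale, offset) pair:  ``p_target = scale * p_source +
offset``.  Coordinates are 0-based pixel centers, x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

__all__ = [
    "FrameTransform",
    "resize_and_pad",
    "gaussian_blur",
    "enhance",
    "map_points",
]


@dataclass(frozen=True)
class FrameTransform:
    """Similarity map between two named coordinate frames.

    Applies ``p' = scale * p + offset`` to (x, y) points.
    """

    scale: float
    offset: tuple[float, float]
    source_frame: str
    target_frame: str

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if pts.size == 0:
            return pts.reshape(0, 2)
        return pts * self.scale + np.asarray(self.offset, dtype=float)

    def invert(self) -> "FrameTransform":
        s = 1.0 / self.scale
        off = (-self.offset[0] * s, -self.offset[1] * s)
        return FrameTransform(s, off, self.target_frame, self.source_frame)

    def compose(self, other: "FrameTransform") -> "FrameTransform":
        """Transform applying ``other`` first, then ``self``."""
        if other.target_frame != self.source_frame:
            raise ValueError(
                f"frame mismatch: {other.target_frame!r} -> {self.source_frame!r}"
            )
        s = self.scale * other.scale
        off = (
            self.scale * other.offset[0] + self.offset[0],
            self.scale * other.offset[1] + self.offset[1],
        )
        return FrameTransform(s, off, other.source_frame, self.target_frame)


def map_points(points: np.ndarray, chain) -> np.ndarray:
    """Push points through a sequence of frame transforms, in order."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    for i, t in enumerate(chain):
        if i > 0 and chain[i - 1].target_frame != t.source_frame:
            raise ValueError(
                f"frame mismatch in chain at position {i}: "
                f"{chain[i - 1].target_frame!r} -> {t.source_frame!r}"
            )
        pts = t.apply(pts)
    return pts


def resize_and_pad(
    image: np.ndarray, target: int = 512, frame: str = "original"
) -> tuple[np.ndarray, FrameTransform]:
    """Scale the longer side to ``target`` and zero-pad right/bottom to square.

    The aspect ratio is preserved exactly; padding pixels are 0.  Content is
    anchored at the top-left corner so the returned original->input transform
    is a pure scale with zero offset.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError(f"expected a nonempty 2-D grayscale raster, got {img.shape}")
    h, w = img.shape
    scale = target / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    if (nh, nw) == (h, w):
        content = img.copy()
    else:
        content = transform.resize(
            img, (nh, nw), order=1, anti_aliasing=scale < 1, preserve_range=True
        )
    out = np.zeros((target, target), dtype=np.float64)
    out[:nh, :nw] = content
    t = FrameTransform(scale, (0.0, 0.0), frame, "input")
    return out, t


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur preserving the [0, 255] intensity range."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    img = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return img.copy()
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(img, sigma=sigma, mode="nearest")


def enhance(
    image: np.ndarray,
    blur_sigma: float = 1.0,
    clahe_clip: float | None = 2.0,
    clahe_tile: int = 8,
) -> np.ndarray:
    """Denoise and boost local contrast: Gaussian blur followed by CLAHE.

    ``clahe_clip`` follows the common cv-style parameterization (values of a
    few units); it is divided by 100 for scikit-image's normalized clip
    limit.  Pass ``clahe_clip=None`` to skip equalization.  Output is float
    in [0, 255] with the same shape as the input.
    """
    if blur_sigma < 0 or clahe_tile <= 0 or (clahe_clip is not None and clahe_clip <= 0):
        raise ValueError("enhancement parameters must be positive")
    img = gaussian_blur(image, blur_sigma)
    if clahe_clip is None:
        return np.clip(img, 0.0, 255.0)
    h, w = img.shape
    kernel = (max(1, h // clahe_tile), max(1, w // clahe_tile))
    eq = exposure.equalize_adapthist(
        np.clip(img, 0, 255).astype(np.uint8),
        kernel_size=kernel,
        clip_limit=clahe_clip / 100.0,
    )
    return eq * 255.0
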
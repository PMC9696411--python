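"""Synthetic lateral lumbar radiograph phantoms with exact ground truth.

Real lateral lumbar X-rays show five stacked lumbar vertebral bodies
(L1..L5) above the sacrum, roughly vertically aligned, each body a bright
convex quadrilateral on a darker soft-tissue background, with the upper
vertebrae frequently occluded by rib/diaphragm shadows.  The phantom
emulates exactly the statistical structure the detector relies on:

* six bodies stacked top to bottom with inter-center spacing about 1/9 of
  the image height (about 7 px at the 64x64 heatmap scale);
* interior mean intensities per vertebra calibrated to measurements from
  real radiographs (L1..L5 means 137.11, 132.20, 130.83, 140.09, 163.02),
  brighter toward L5, with a configurable sacrum value;
* the sacrum rendered as a tilted wedge whose only annotated points are the
  two endpoints of its upper end plate;
* optional darkening bands over a random upper vertebra (L1..L4) emulating
  partial occlusion, plus Gaussian pixel noise.

Annotations (6 centers; 4 corner landmarks per lumbar vertebra, ordered
top-left, top-right, bottom-left, bottom-right; 2 sacrum end-plate points)
match the drawn geometry exactly, so every downstream module is testable
without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon as draw_polygon

__all__ = [
    "LUMBAR_LABELS",
    "VERTEBRA_LABELS",
    "TABLE1_INTERIOR_MEANS",
    "PhantomSpec",
    "AnnotatedImage",
    "generate_phantom",
    "generate_dataset",
]

LUMBAR_LABELS = ("L1", "L2", "L3", "L4", "L5")
VERTEBRA_LABELS = LUMBAR_LABELS + ("S1",)

#: Mean interior intensity of each lumbar body measured on real lateral
#: radiographs; the phantom's default calibration.  S1 is not part of the
#: measured set and defaults to a slightly brighter 170.
TABLE1_INTERIOR_MEANS = {
    "L1": 137.11,
    "L2": 132.20,
    "L3": 130.83,
    "L4": 140.09,
    "L5": 163.02,
    "S1": 170.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom population.

    Intensities are on the 8-bit [0, 255] scale; lengths in pixels of the
    original frame; ``tilt_sd`` in degrees.  ``occlusion_band`` is
    (band height as a fraction of vertebra height, darkening factor).
    """

    image_height: int = 640
    image_width: int = 512
    n_vertebrae: int = 6
    inter_center_spacing: float = 71.0
    spacing_jitter_sd: float = 3.0
    vertebra_width: float = 58.0
    width_jitter_sd: float = 4.0
    vertebra_height: float = 48.0
    height_jitter_sd: float = 3.0
    center_jitter_sd: float = 10.0
    interior_means: tuple[float, ...] = tuple(
        TABLE1_INTERIOR_MEANS[k] for k in VERTEBRA_LABELS
    )
    background_mean: float = 90.0
    noise_sd: float = 8.0
    occlusion_prob: float = 0.35
    occlusion_band: tuple[float, float] = (0.8, 0.45)
    tilt_sd: float = 4.0
    s1_tilt: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae != 6:
            raise ValueError("the detector is defined for exactly 6 vertebrae (L1-L5 + S1)")
        if len(self.interior_means) != 6:
            raise ValueError("interior_means must have 6 entries (L1..L5, S1)")
        for v in (*self.interior_means, self.background_mean):
            if not 0 <= v <= 255:
                raise ValueError(f"intensity {v} outside [0, 255]")
        if not 0 <= self.occlusion_prob <= 1:
            raise ValueError("occlusion_prob must be in [0, 1]")
        if self.inter_center_spacing <= 0:
            raise ValueError("inter_center_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class AnnotatedImage:
    """Grayscale raster plus exact ground-truth geometry in a named frame.

    ``centers`` are 6 ordered points (L1..L5, S1) with strictly increasing
    y.  ``landmarks`` maps each lumbar label to its 4 corners in the order
    (top-left, top-right, bottom-left, bottom-right) and "S1" to the upper
    end plate's (left, right) endpoints.  ``vertebra_boxes`` are axis-aligned
    (x0, y0, x1, y1) bounds per label, used by the cutout augmentation.
    """

    pixels: np.ndarray
    frame: str
    centers: np.ndarray
    landmarks: dict[str, np.ndarray]
    vertebra_boxes: dict[str, tuple[float, float, float, float]]
    occluded: bool = False

    def copy(self) -> "AnnotatedImage":
        return AnnotatedImage(
            pixels=self.pixels.copy(),
            frame=self.frame,
            centers=self.centers.copy(),
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            vertebra_boxes=dict(self.vertebra_boxes),
            occluded=self.occluded,
        )

    def annotation_dict(self, image_name: str) -> dict:
        return {
            "image": image_name,
            "frame": self.frame,
            "centers": [[float(x), float(y)] for x, y in self.centers],
            "landmarks": {
                label: [[float(x), float(y)] for x, y in self.landmarks[label]]
                for label in VERTEBRA_LABELS
            },
        }


def _lumbar_corners(center, width, height, tilt_deg):
    """Corners (Lt, Rt, Lb, Rb) of a rotated rectangle around ``center``."""
    t = np.deg2rad(tilt_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    local = np.array(
        [
            [-width / 2, -height / 2],
            [width / 2, -height / 2],
            [-width / 2, height / 2],
            [width / 2, height / 2],
        ]
    )
    return local @ rot.T + np.asarray(center)


def _fill_polygon(img, corners_xy, value):
    rr, cc = draw_polygon(corners_xy[:, 1], corners_xy[:, 0], shape=img.shape)
    img[rr, cc] = value


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> AnnotatedImage:
    """Draw one phantom; deterministic for a fixed (spec, seed)."""
    if seed is None:
        seed = spec.seed
    h, w = spec.image_height, spec.image_width
    needed = 5 * spec.inter_center_spacing + 2.0 * spec.vertebra_height
    if h < needed or w < 1.2 * spec.vertebra_width:
        raise ValueError(
            f"raster {h}x{w} too small for 6 vertebrae at spacing "
            f"{spec.inter_center_spacing} (needs height >= {needed:.0f})"
        )
    rng = np.random.default_rng(seed)

    spacings = spec.inter_center_spacing + rng.normal(0, 1, 5) * spec.spacing_jitter_sd
    spacings = np.clip(spacings, 0.3 * spec.inter_center_spacing, None)
    y0 = (h - 5 * spec.inter_center_spacing) / 2 + rng.normal(0, 1) * spec.center_jitter_sd
    ys = y0 + np.concatenate([[0.0], np.cumsum(spacings)])
    xs = w / 2 + rng.normal(0, 1, 6) * spec.center_jitter_sd
    centers = np.stack([xs, ys], axis=1)

    img = np.full((h, w), spec.background_mean, dtype=np.float64)
    landmarks: dict[str, np.ndarray] = {}
    boxes: dict[str, tuple[float, float, float, float]] = {}

    for i, label in enumerate(LUMBAR_LABELS):
        vw = max(10.0, spec.vertebra_width + rng.normal(0, 1) * spec.width_jitter_sd)
        vh = max(8.0, spec.vertebra_height + rng.normal(0, 1) * spec.height_jitter_sd)
        tilt = rng.normal(0, 1) * spec.tilt_sd
        corners = _lumbar_corners(centers[i], vw, vh, tilt)
        # recenter so the annotated center is exactly the corner mean
        corners += centers[i] - corners.mean(axis=0)
        corners = np.clip(corners, [1.0, 1.0], [w - 2.0, h - 2.0])
        _fill_polygon(img, corners[[0, 1, 3, 2]], spec.interior_means[i])
        landmarks[label] = corners
        boxes[label] = (
            float(corners[:, 0].min()),
            float(corners[:, 1].min()),
            float(corners[:, 0].max()),
            float(corners[:, 1].max()),
        )

    # S1: a tilted wedge below L5; only the upper end plate is annotated.
    s1w = max(10.0, 0.7 * spec.vertebra_width + rng.normal(0, 1) * spec.width_jitter_sd)
    s1h = max(10.0, 1.2 * spec.vertebra_height + rng.normal(0, 1) * spec.height_jitter_sd)
    s1_tilt = spec.s1_tilt + rng.normal(0, 1) * spec.tilt_sd
    t = np.deg2rad(s1_tilt)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    plate = np.array([[-s1w / 2, -s1h / 2], [s1w / 2, -s1h / 2]]) @ rot.T + centers[5]
    tip = np.array([0.1 * s1w, s1h / 2]) @ rot.T + centers[5]
    plate = np.clip(plate, [1.0, 1.0], [w - 2.0, h - 2.0])
    tip = np.clip(tip, [1.0, 1.0], [w - 2.0, h - 2.0])
    wedge = np.vstack([plate, tip[None, :]])
    _fill_polygon(img, wedge, spec.interior_means[5])
    order = np.argsort(plate[:, 0])
    landmarks["S1"] = plate[order]
    boxes["S1"] = (
        float(wedge[:, 0].min()),
        float(wedge[:, 1].min()),
        float(wedge[:, 0].max()),
        float(wedge[:, 1].max()),
    )

    occluded = False
    if rng.random() < spec.occlusion_prob:
        occluded = True
        k = rng.integers(0, 4)  # one of L1..L4
        frac, factor = spec.occlusion_band
        x0, by0, x1, by1 = boxes[LUMBAR_LABELS[k]]
        band_h = frac * (by1 - by0)
        band_c = rng.uniform(by0, by1)
        r0 = max(0, int(round(band_c - band_h / 2)))
        r1 = min(h, int(round(band_c + band_h / 2)) + 1)
        img[r0:r1, :] *= factor

    if spec.noise_sd > 0:
        img += rng.normal(0, 1, img.shape) * spec.noise_sd
    img = np.clip(img, 0.0, 255.0)

    return AnnotatedImage(
        pixels=img,
        frame="original",
        centers=centers,
        landmarks=landmarks,
        vertebra_boxes=boxes,
        occluded=occluded,
    )


def generate_dataset(
    spec: PhantomSpec, n: int, seed: int, out_dir: str | Path
) -> dict:
    """Write ``n`` phantom PNGs + annotation JSONs + a manifest; return it."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    for i in range(n):
        sample = generate_phantom(spec, int(child_seeds[i]))
        name = f"phantom_{i:05d}"
        img_path = out / f"{name}.png"
        ann_path = out / f"{name}.json"
        iio.imwrite(img_path, np.round(sample.pixels).astype(np.uint8))
        ann_path.write_text(
            json.dumps(sample.annotation_dict(img_path.name), indent=1, sort_keys=True)
        )
        entries.append(
            {
                "image": img_path.name,
                "annotation": ann_path.name,
                "occluded": sample.occluded,
                "seed": int(child_seeds[i]),
            }
        )
    manifest = {"n": n, "seed": seed, "images": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_annotation(path: str | Path) -> AnnotatedImage:
    """Read an (image, annotation JSON) pair back into an AnnotatedImage."""
    path = Path(path)
    ann = json.loads(path.read_text())
    img = iio.imread(path.parent / ann["image"]).astype(np.float64)
    landmarks = {k: np.asarray(v, dtype=float) for k, v in ann["landmarks"].items()}
    boxes = {}
    for label in VERTEBRA_LABELS:
        pts = landmarks[label]
        boxes[label] = (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )
    return AnnotatedImage(
        pixels=img,
        frame=ann["frame"],
        centers=np.asarray(ann["centers"], dtype=float),
        landmarks=landmarks,
        vertebra_boxes=boxes,
    )
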
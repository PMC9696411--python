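"""End-to-end orchestration: phantoms -> center net -> repair -> crops ->
landmark nets -> evaluation.

Frames used throughout (all similarity-related, see ``prep``):

* ``original`` — the raw raster; ``padded`` — the same raster zero-padded
  to a square (content anchored top-left, so coordinates coincide with
  ``original``);
* ``input`` — the 512x512 preprocessed network input (pure scale from
  original);
* ``heatmap`` — the 64x64 center-map grid, exactly input/8;
* ``crop`` — a 256x256 per-vertebra window in padded coordinates.

Training crops are built around *ground-truth* centers (with optional
random translation jitter standing in for center-prediction error);
inference crops around *predicted* centers.  That asymmetry is the
documented training protocol, enforced here by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .augment import AugmentConfig, photometric_geometric, random_spine_cutout
from .centernet import CenterNet, CenterNetConfig, train_centernet
from .landmarknet import (
    LUMBAR_CHANNELS,
    SACRUM_CHANNELS,
    LandmarkNet,
    LandmarkNetConfig,
    decode_landmarks,
    train_landmarknet,
)
from .metrics import center_report, landmark_report
from .phantom import (
    LUMBAR_LABELS,
    VERTEBRA_LABELS,
    AnnotatedImage,
    PhantomSpec,
    generate_phantom,
)
from .postprocess import (
    CropSpec,
    crop_sizes,
    crop_vertebra,
    extract_maxima,
    gap_check,
    repair_centers,
)
from .prep import FrameTransform, enhance, map_points, resize_and_pad
from .targets import gaussian_map, lumbar_segments, paf_map, sacrum_segment, sigma_for

__all__ = ["PipelineConfig", "Models", "prepare_center_sample", "prepare_crop_samples",
           "build_center_dataset", "build_crop_dataset", "infer_image", "run_experiment"]

HEATMAP_SCALE = 8  # input -> heatmap downsampling factor


@dataclass
class PipelineConfig:
    """Single source of truth for a full run; YAML-round-trippable."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    centernet: CenterNetConfig = field(default_factory=CenterNetConfig)
    lumbar: LandmarkNetConfig = field(default_factory=lambda: LandmarkNetConfig(kind="lumbar"))
    sacrum: LandmarkNetConfig = field(default_factory=lambda: LandmarkNetConfig(kind="sacrum"))
    center_train: nn.TrainConfig = field(default_factory=nn.TrainConfig)
    landmark_train: nn.TrainConfig = field(
        default_factory=lambda: nn.TrainConfig(batch=32, max_epochs=250, patience=25)
    )
    blur_sigma: float = 1.0
    clahe_clip: float | None = 2.0
    clahe_tile: int = 8
    paf_width: float = 4.0
    crop_jitter_sd: float = 4.0  # px, train-time stand-in for center error
    augment_train: bool = True
    n_train: int = 200
    n_val: int = 40
    n_test: int = 50
    max_lumbar_crops: int = 400
    max_sacrum_crops: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sub = {
            "phantom": PhantomSpec,
            "augment": AugmentConfig,
            "centernet": CenterNetConfig,
            "lumbar": LandmarkNetConfig,
            "sacrum": LandmarkNetConfig,
            "center_train": nn.TrainConfig,
            "landmark_train": nn.TrainConfig,
        }
        for key, value in raw.items():
            if key in sub:
                if isinstance(value, dict):
                    value = {
                        k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                    }
                    kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class Models:
    center: CenterNet
    lumbar: LandmarkNet
    sacrum: LandmarkNet


# ---------------------------------------------------------------------------
# dataset construction


def _normalize(img: np.ndarray) -> np.ndarray:
    return (img / 255.0 - 0.5).astype(np.float32)


def prepare_center_sample(
    sample: AnnotatedImage, cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, FrameTransform]:
    """Preprocess one annotated image into (net input, target stack, transform)."""
    inp, t = resize_and_pad(sample.pixels, cfg.centernet.in_size)
    inp = enhance(inp, cfg.blur_sigma, cfg.clahe_clip, cfg.clahe_tile)
    hm_t = FrameTransform(1.0 / HEATMAP_SCALE, (0.0, 0.0), "input", "heatmap")
    centers_hm = map_points(sample.centers, [t, hm_t])
    l5_hm = map_points(sample.landmarks["L5"], [t, hm_t])
    sigma = sigma_for("center", l5_hm)
    size = cfg.centernet.out_size
    stack = gaussian_map(
        centers_hm, sigma, (size, size), frame="heatmap", channel_labels=VERTEBRA_LABELS
    )
    return _normalize(inp)[None], stack.maps.astype(np.float32), t


def build_center_dataset(samples, cfg: PipelineConfig, rng=None, augment=False):
    """Center-net training pairs; optional cutout/photometric augmentation."""
    rng = rng or np.random.default_rng(cfg.seed)
    out = []
    for sample in samples:
        s = sample
        if augment:
            if rng.random() < 0.5:
                s = photometric_geometric(s, cfg.augment, rng)
            if rng.random() < cfg.augment.rsc_prob:
                s = random_spine_cutout(s, cfg.augment, rng)
        img, gt, _ = prepare_center_sample(s, cfg)
        out.append((img, gt))
    return out


def _pad_square(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    side = max(h, w)
    out = np.zeros((side, side), dtype=np.float64)
    out[:h, :w] = image
    return out


def prepare_crop_samples(
    sample: AnnotatedImage,
    cfg: PipelineConfig,
    kind: str,
    rng: np.random.Generator | None = None,
):
    """Per-vertebra training crops from ground-truth centers.

    Returns a list of (crop input, gt confidence maps, gt PAF) triples,
    one per lumbar vertebra or one for the sacrum.  When ``rng`` is given,
    crop centers are jittered by ``crop_jitter_sd`` to emulate
    center-prediction error at inference time.
    """
    labels = LUMBAR_LABELS if kind == "lumbar" else ("S1",)
    padded = _pad_square(sample.pixels)
    sides = crop_sizes(sample.centers)
    out_size = (cfg.lumbar if kind == "lumbar" else cfg.sacrum).in_size
    triples = []
    for label in labels:
        i = VERTEBRA_LABELS.index(label)
        center = sample.centers[i].copy()
        if rng is not None and cfg.crop_jitter_sd > 0:
            center = center + rng.normal(0, cfg.crop_jitter_sd, 2)
        spec = CropSpec(center=tuple(center), side=float(sides[i]), label=label)
        crop, t = crop_vertebra(padded, spec, out_size, cfg.blur_sigma, source_frame="padded")
        inv = t.invert()
        pts = inv.apply(sample.landmarks[label])
        if not ((0 <= pts).all() and (pts <= out_size - 1).all()):
            continue  # jitter pushed a landmark out of the window
        if label == "S1":
            sigma = sigma_for("sacrum", pts)
            segments = sacrum_segment(pts)
            channels = SACRUM_CHANNELS
        else:
            sigma = sigma_for("lumbar", pts)
            segments = lumbar_segments(pts)
            channels = LUMBAR_CHANNELS
        cm = gaussian_map(pts, sigma, (out_size, out_size), frame="crop", channel_labels=channels)
        paf = paf_map(segments, cfg.paf_width, (out_size, out_size))
        triples.append(
            (
                _normalize(crop)[None],
                cm.maps.astype(np.float32),
                paf.map.astype(np.float32),
            )
        )
    return triples


def build_crop_dataset(samples, cfg: PipelineConfig, kind: str, rng=None, limit=None):
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    out = []
    for sample in samples:
        out.extend(prepare_crop_samples(sample, cfg, kind, rng))
    if limit is not None and len(out) > limit:
        idx = np.random.default_rng(cfg.seed + 2).permutation(len(out))[:limit]
        out = [out[i] for i in idx]
    return out


# ---------------------------------------------------------------------------
# inference


def infer_image(image: np.ndarray, models: Models, cfg: PipelineConfig) -> dict:
    """Full chain on one grayscale raster; results in the original frame."""
    inp, t = resize_and_pad(image, cfg.centernet.in_size)
    inp = enhance(inp, cfg.blur_sigma, cfg.clahe_clip, cfg.clahe_tile)
    cmaps = models.center.predict(_normalize(inp)[None, None])[0]
    maxima = extract_maxima(cmaps)
    gap = gap_check(maxima)
    repaired = False
    centers_hm = maxima
    if gap.flagged:
        centers_hm, repaired = repair_centers(cmaps, gap)
    hm_to_input = FrameTransform(float(HEATMAP_SCALE), (0.0, 0.0), "heatmap", "input")
    centers_input = hm_to_input.apply(centers_hm)
    centers_orig = t.invert().apply(centers_input)

    padded = _pad_square(image)
    try:
        sides = crop_sizes(centers_orig)
    except ValueError:
        # degenerate prediction (coincident neighbor y's); substitute the
        # mean positive gap so inference still produces a full result
        gaps = np.abs(np.diff(centers_orig[:, 1]))
        fallback = float(gaps[gaps > 0].mean()) if (gaps > 0).any() else 64.0
        y = centers_orig[:, 1].copy()
        y += np.arange(6) * 1e-6  # break exact ties
        safe = np.maximum(np.abs(np.diff(y)), 0.25 * fallback)
        sides = np.empty(6)
        sides[0] = 1.5 * safe[0]
        sides[1:4] = 0.75 * (safe[0:3] + safe[1:4])
        sides[4] = 1.5 * safe[3]
        sides[5] = 1.5 * safe[3]
    out_size = cfg.lumbar.in_size
    landmarks: dict[str, np.ndarray] = {}
    for i, label in enumerate(VERTEBRA_LABELS):
        cx = float(np.clip(centers_orig[i, 0], 0, padded.shape[1] - 1))
        cy = float(np.clip(centers_orig[i, 1], 0, padded.shape[0] - 1))
        spec = CropSpec(center=(cx, cy), side=float(sides[i]), label=label)
        crop, ct = crop_vertebra(padded, spec, out_size, cfg.blur_sigma, source_frame="padded")
        net = models.sacrum if label == "S1" else models.lumbar
        cm, _ = net.predict(_normalize(crop)[None, None])
        landmarks[label] = decode_landmarks(cm[0], ct)
    return {
        "centers": centers_orig,
        "centers_raw": t.invert().apply(hm_to_input.apply(maxima)),
        "centers_input": centers_input,
        "input_transform": t,
        "landmarks": landmarks,
        "gap_flagged": bool(gap.flagged),
        "repaired": repaired,
    }


# ---------------------------------------------------------------------------
# experiment


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def run_experiment(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Reproducible end-to-end run: generate, train both stages, evaluate.

    Returns (and optionally writes) a report with center distance
    statistics (inlier/all, at the 512 input scale), the crop outlier
    ratio, and per-vertebra landmark D/RD statistics in the original frame.
    """
    seeds = _spawn_seeds(cfg.seed, 6)
    train = [generate_phantom(cfg.phantom, s) for s in _spawn_seeds(seeds[0], cfg.n_train)]
    val = [generate_phantom(cfg.phantom, s) for s in _spawn_seeds(seeds[1], cfg.n_val)]
    test = [generate_phantom(cfg.phantom, s) for s in _spawn_seeds(seeds[2], cfg.n_test)]

    rng = np.random.default_rng(seeds[3])
    center_train_set = build_center_dataset(train, cfg, rng, augment=cfg.augment_train)
    center_val_set = build_center_dataset(val, cfg)
    cnet, center_hist = train_centernet(
        center_train_set, cfg.centernet, cfg.center_train, val_set=center_val_set
    )

    lrng = np.random.default_rng(seeds[4])
    lum_train = build_crop_dataset(train, cfg, "lumbar", lrng, limit=cfg.max_lumbar_crops)
    lum_val = build_crop_dataset(val, cfg, "lumbar", None, limit=max(20, cfg.max_lumbar_crops // 8))
    lnet, lum_hist = train_landmarknet(lum_train, cfg.lumbar, cfg.landmark_train, val_set=lum_val)
    sac_train = build_crop_dataset(train, cfg, "sacrum", lrng, limit=cfg.max_sacrum_crops)
    sac_val = build_crop_dataset(val, cfg, "sacrum", None)
    snet, sac_hist = train_landmarknet(sac_train, cfg.sacrum, cfg.landmark_train, val_set=sac_val)

    models = Models(center=cnet, lumbar=lnet, sacrum=snet)

    preds = [infer_image(s.pixels, models, cfg) for s in test]
    pred_centers_input = [p["centers_input"] for p in preds]
    gt_centers_input = [p["input_transform"].apply(s.centers) for p, s in zip(preds, test)]
    gt_landmarks_input = [
        {k: p["input_transform"].apply(v) for k, v in s.landmarks.items()}
        for p, s in zip(preds, test)
    ]
    c_report = center_report(pred_centers_input, gt_centers_input, gt_landmarks_input)
    l_report = landmark_report([p["landmarks"] for p in preds], [s.landmarks for s in test])

    report = {
        "n_train": cfg.n_train,
        "n_test": cfg.n_test,
        "center": c_report,
        "landmarks": l_report.as_dict(),
        "repair_fired": int(sum(p["repaired"] for p in preds)),
        "gap_flagged": int(sum(p["gap_flagged"] for p in preds)),
        "center_epochs": len(center_hist["train_loss"]),
        "lumbar_epochs": len(lum_hist["train_loss"]),
        "sacrum_epochs": len(sac_hist["train_loss"]),
        "history": {
            "center": center_hist,
            "lumbar": lum_hist,
            "sacrum": sac_hist,
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
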
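"""Evaluation statistics: distance errors, relative distances, outliers.

Two outlier notions coexist and are kept separate deliberately:

* **center stage**: an image is an outlier when the square crops built
  from *predicted* centers fail to contain at least one ground-truth
  landmark — the landmark stage never sees that vertebra, so distance
  error alone understates the failure.  Center distance statistics are
  reported both excluding outlier images ("inlier") and over all images.
* **landmark stage**: a vertebra is an outlier when the mean relative
  distance error of its landmarks exceeds 20%, roughly the distance to the
  neighboring vertebra's nearest landmark.

The relative distance (RD) error normalizes by local vertebra dimensions:
for a lumbar corner, the x-residual by the length h of the end-plate edge
incident to the ground-truth corner and the y-residual by the side edge
length v, ``RD = 100 * sqrt((dx/h)^2 + (dy/v)^2)``; for a sacrum point,
``RD = 100 * ||pred - gt|| / l`` with l the end-plate length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import LUMBAR_LABELS, VERTEBRA_LABELS
from .postprocess import crop_sizes

__all__ = [
    "RDReport",
    "rd_lumbar",
    "rd_sacrum",
    "lumbar_normalizers",
    "center_report",
    "landmark_report",
]

OUTLIER_RD_PERCENT = 20.0


def rd_lumbar(pred, gt, h: float, v: float) -> float:
    """Relative distance error (%) of one lumbar corner."""
    if h <= 0 or v <= 0:
        raise ValueError("normalizing edge lengths must be positive")
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    rx = (pred[0] - gt[0]) / h
    ry = (pred[1] - gt[1]) / v
    return 100.0 * float(np.hypot(rx, ry))


def rd_sacrum(pred, gt, l: float) -> float:
    """Relative distance error (%) of one sacrum end-plate point."""
    if l <= 0:
        raise ValueError("sacrum length must be positive")
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    return 100.0 * float(np.linalg.norm(pred - gt)) / l


def lumbar_normalizers(corners: np.ndarray) -> list[tuple[float, float]]:
    """(h, v) per corner in (Lt, Rt, Lb, Rb) order, from ground-truth edges.

    h is the end-plate edge incident to the corner (Lt-Rt or Lb-Rb), v the
    side edge (Lt-Lb or Rt-Rb).
    """
    c = np.asarray(corners, dtype=float)
    top = float(np.linalg.norm(c[0] - c[1]))
    bottom = float(np.linalg.norm(c[2] - c[3]))
    left = float(np.linalg.norm(c[0] - c[2]))
    right = float(np.linalg.norm(c[1] - c[3]))
    return [(top, left), (top, right), (bottom, left), (bottom, right)]


@dataclass
class RDReport:
    """Per-vertebra landmark error summary with the 20% outlier rule."""

    per_vertebra: dict  # label -> {"d_mean","d_sd","rd_mean","rd_sd","outlier_ratio"}
    total_d_mean: float
    total_d_sd: float
    total_rd_mean: float
    total_rd_sd: float
    outlier_ratio: float  # % of (image, vertebra) cases over the 20% rule
    accuracy: float  # 100 - outlier_ratio

    def as_dict(self) -> dict:
        return {
            "per_vertebra": self.per_vertebra,
            "total": {
                "d_mean": self.total_d_mean,
                "d_sd": self.total_d_sd,
                "rd_mean": self.total_rd_mean,
                "rd_sd": self.total_rd_sd,
            },
            "outlier_ratio_percent": self.outlier_ratio,
            "accuracy_percent": self.accuracy,
        }


def _crops_contain_landmarks(pred_centers: np.ndarray, gt_landmarks: dict) -> bool:
    """True iff every vertebra's ground-truth landmarks lie inside the
    square crop built from the predicted centers (the crop-stage contract).
    Predictions too degenerate to define crops (coincident neighbor y's)
    count as not containing."""
    try:
        sides = crop_sizes(pred_centers)
    except ValueError:
        return False
    for i, label in enumerate(VERTEBRA_LABELS):
        cx, cy = pred_centers[i]
        half = sides[i] / 2.0
        pts = np.asarray(gt_landmarks[label], dtype=float)
        if (
            (pts[:, 0] < cx - half).any()
            or (pts[:, 0] > cx + half).any()
            or (pts[:, 1] < cy - half).any()
            or (pts[:, 1] > cy + half).any()
        ):
            return False
    return True


def center_report(pred_centers_list, gt_centers_list, gt_landmarks_list) -> dict:
    """Center distance statistics with crop-based outlier accounting.

    All three arguments are matched per-image sequences.  Returns per-
    vertebra and total mean(sd) distance for inlier images and for all
    images, plus the outlier ratio in percent.
    """
    n = len(pred_centers_list)
    if not (n == len(gt_centers_list) == len(gt_landmarks_list)):
        raise ValueError("prediction/annotation sequences must be matched")
    dists = np.empty((n, 6))
    inlier = np.empty(n, dtype=bool)
    for i, (pred, gt, lms) in enumerate(
        zip(pred_centers_list, gt_centers_list, gt_landmarks_list)
    ):
        pred = np.asarray(pred, dtype=float)
        gt = np.asarray(gt, dtype=float)
        if pred.shape != (6, 2) or gt.shape != (6, 2):
            raise ValueError("centers must be 6 ordered points")
        dists[i] = np.linalg.norm(pred - gt, axis=1)
        inlier[i] = _crops_contain_landmarks(pred, lms)

    def summary(mask):
        sub = dists[mask]
        if sub.size == 0:
            return {label: (float("nan"), float("nan")) for label in VERTEBRA_LABELS} | {
                "total": (float("nan"), float("nan"))
            }
        out = {
            label: (float(sub[:, k].mean()), float(sub[:, k].std()))
            for k, label in enumerate(VERTEBRA_LABELS)
        }
        out["total"] = (float(sub.mean()), float(sub.std()))
        return out

    return {
        "inlier": summary(inlier),
        "all": summary(np.ones(n, dtype=bool)),
        "outlier_ratio_percent": 100.0 * float((~inlier).sum()) / n,
        "n_images": n,
        "n_outliers": int((~inlier).sum()),
    }


def landmark_report(preds, gts) -> RDReport:
    """Landmark D/RD statistics and per-vertebra 20%-rule outlier flags.

    ``preds``/``gts`` are matched per-image dicts mapping "L1".."L5" to 4
    corner points and "S1" to 2 end-plate points (ground truth also sets
    the normalizing edge lengths).  Labels absent from a prediction are
    skipped, so center-stage outliers can be excluded upstream.
    """
    if len(preds) == 0 or len(preds) != len(gts):
        raise ValueError("need matched, nonempty prediction/annotation sequences")
    d_all: dict[str, list[float]] = {label: [] for label in VERTEBRA_LABELS}
    rd_all: dict[str, list[float]] = {label: [] for label in VERTEBRA_LABELS}
    flags: dict[str, list[bool]] = {label: [] for label in VERTEBRA_LABELS}
    for pred, gt in zip(preds, gts):
        for label in VERTEBRA_LABELS:
            if label not in pred:
                continue
            p = np.asarray(pred[label], dtype=float)
            g = np.asarray(gt[label], dtype=float)
            if label in LUMBAR_LABELS:
                norms = lumbar_normalizers(g)
                rds = [rd_lumbar(p[k], g[k], *norms[k]) for k in range(4)]
            else:
                l = float(np.linalg.norm(g[0] - g[1]))
                rds = [rd_sacrum(p[k], g[k], l) for k in range(2)]
            ds = list(np.linalg.norm(p - g, axis=1))
            d_all[label] += ds
            rd_all[label] += rds
            flags[label].append(float(np.mean(rds)) > OUTLIER_RD_PERCENT)

    per_vertebra = {}
    for label in VERTEBRA_LABELS:
        ds = np.asarray(d_all[label])
        rds = np.asarray(rd_all[label])
        fl = np.asarray(flags[label], dtype=bool)
        per_vertebra[label] = {
            "d_mean": float(ds.mean()) if ds.size else float("nan"),
            "d_sd": float(ds.std()) if ds.size else float("nan"),
            "rd_mean": float(rds.mean()) if rds.size else float("nan"),
            "rd_sd": float(rds.std()) if rds.size else float("nan"),
            "outlier_ratio": 100.0 * float(fl.mean()) if fl.size else float("nan"),
            "n_cases": int(fl.size),
        }
    all_d = np.asarray([x for v in d_all.values() for x in v])
    all_rd = np.asarray([x for v in rd_all.values() for x in v])
    all_fl = np.asarray([x for v in flags.values() for x in v], dtype=bool)
    ratio = 100.0 * float(all_fl.mean()) if all_fl.size else float("nan")
    return RDReport(
        per_vertebra=per_vertebra,
        total_d_mean=float(all_d.mean()),
        total_d_sd=float(all_d.std()),
        total_rd_mean=float(all_rd.mean()),
        total_rd_sd=float(all_rd.std()),
        outlier_ratio=ratio,
        accuracy=100.0 - ratio,
    )
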
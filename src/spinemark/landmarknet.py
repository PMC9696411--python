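"""Corner-landmark detectors for vertebra crops (lumbar and sacrum heads).

Each 256x256 crop around one detected center is passed through an M-Net
style encoder-decoder: multi-scale downsampled copies of the input are
injected at every encoder stage, skip connections feed the decoder, and all
blocks use the pre-activation ordering.  Two networks share the template
and differ only in the output head:

* lumbar: 5 channels = 4 corner confidence maps (Lt, Rt, Lb, Rb) + 1 part
  affinity field channel covering both end plates;
* sacrum: 3 channels = 2 end-plate point maps (L, R) + 1 PAF channel.

The first ``coordconv_stages`` encoder stages use CoordConv: two constant
coordinate channels, normalized to [-1, 1], are concatenated before the
convolution.  This deliberately breaks translation equivariance so the net
can learn that crops are center-aligned and corners live in predictable
regions — which is what lets it place an occluded corner from the learned
location prior.

The PAF head is one extra output channel on the shared trunk, so enabling
it costs exactly one channel's worth of head weights.  Loss:
``(1/K) sum_i ||CM_i - CM_i_hat||^2 + lambda ||PAF - PAF_hat||^2`` with
lambda = alpha = 0.001 (lumbar) or beta = 0.01 (sacrum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .prep import FrameTransform

__all__ = [
    "LandmarkNetConfig",
    "LandmarkNet",
    "coord_channels",
    "build_landmarknet",
    "landmark_loss",
    "decode_landmarks",
    "train_landmarknet",
]

LUMBAR_CHANNELS = ("Lt", "Rt", "Lb", "Rb")
SACRUM_CHANNELS = ("L", "R")


@dataclass(frozen=True)
class LandmarkNetConfig:
    kind: str = "lumbar"
    base_channels: int = 8
    coordconv_stages: int = 2
    depth: int = 4
    in_size: int = 256
    multiscale_inputs: bool = True
    preactivation: bool = True
    norm: str = "instance"
    alpha: float = 0.001
    beta: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lumbar", "sacrum"):
            raise ValueError("kind must be 'lumbar' or 'sacrum'")
        if not 0 <= self.coordconv_stages <= self.depth:
            raise ValueError("coordconv_stages must be within the encoder depth")
        if self.depth < 2:
            raise ValueError("need at least 2 encoder stages")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def n_cm(self) -> int:
        return 4 if self.kind == "lumbar" else 2

    @property
    def out_channels(self) -> int:
        return self.n_cm + 1

    @property
    def paf_weight(self) -> float:
        return self.alpha if self.kind == "lumbar" else self.beta


def coord_channels(height: int, width: int) -> np.ndarray:
    """(2, H, W) constant rasters: x then y, linear from -1 to 1, corners exact."""
    if height < 2 or width < 2:
        raise ValueError("coordinate channels need at least 2 pixels per axis")
    x = np.linspace(-1.0, 1.0, width, dtype=np.float32)
    y = np.linspace(-1.0, 1.0, height, dtype=np.float32)
    cx = np.broadcast_to(x[None, :], (height, width))
    cy = np.broadcast_to(y[:, None], (height, width))
    return np.stack([cx, cy])


class LandmarkNet:
    def __init__(self, cfg: LandmarkNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        widths = [c] + [2 * c] * (cfg.depth - 1)
        pre = cfg.preactivation
        mk = lambda ci, co, k, preact=pre: nn.ConvLayer(
            ci, co, k, rng=rng, preact=preact, norm=cfg.norm
        )
        self.enc = []
        for i in range(cfg.depth):
            cin = 1 if i == 0 else widths[i - 1]
            if i > 0 and cfg.multiscale_inputs:
                cin += 1
            if i < cfg.coordconv_stages:
                cin += 2
            self.enc.append(mk(cin, widths[i], 3, preact=pre and i > 0))
        self.bott = mk(widths[-1], widths[-1], 3)
        self.dec = []
        for i in reversed(range(cfg.depth)):
            cin = (widths[i + 1] if i + 1 < cfg.depth else widths[-1]) + widths[i]
            self.dec.append(mk(cin, widths[i], 3))
        self.head = mk(widths[0], cfg.out_channels, 1)
        self._coords: dict[tuple[int, int], np.ndarray] = {}

    def layers(self):
        return [*self.enc, self.bott, *self.dec, self.head]

    def params(self):
        return [p for layer in self.layers() for p in layer.params()]

    def n_params(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def _coord_batch(self, n: int, h: int, w: int) -> np.ndarray:
        key = (h, w)
        if key not in self._coords:
            self._coords[key] = np.ascontiguousarray(
                coord_channels(h, w).transpose(1, 2, 0)
            )
        return np.broadcast_to(self._coords[key][None], (n, h, w, 2))

    def forward(self, x: np.ndarray) -> nn.Tensor:
        """x: (N, 1, 256, 256) -> NHWC tensor (N, 256, 256, out_channels)."""
        cfg = self.cfg
        t = nn.Tensor(np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1))
        scaled = t
        f = t
        skips = []
        for i, layer in enumerate(self.enc):
            parts = [f]
            if i > 0:
                scaled = nn.avgpool2x(scaled)  # input copy at this scale
                if cfg.multiscale_inputs:
                    parts.append(scaled)
            if i < cfg.coordconv_stages:
                n, h, w, _ = parts[0].v.shape
                parts.append(nn.Tensor(self._coord_batch(n, h, w)))
            f = layer(nn.concat(parts) if len(parts) > 1 else f)
            skips.append(f)
            f = nn.avgpool2x(f)
        f = self.bott(f)
        for layer, skip in zip(self.dec, reversed(skips)):
            f = nn.upsample2x(f)
            f = layer(nn.concat([f, skip]))
        return self.head(f)

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference: (confidence maps (N,K,256,256), paf (N,256,256))."""
        out = self.forward(x).v.transpose(0, 3, 1, 2)
        k = self.cfg.n_cm
        return np.clip(out[:, :k], 0.0, 1.0), np.clip(out[:, k], 0.0, 1.0)


def build_landmarknet(cfg: LandmarkNetConfig) -> LandmarkNet:
    return LandmarkNet(cfg)


def _landmark_loss_t(out: nn.Tensor, gt_cm: np.ndarray, gt_paf: np.ndarray, cfg: LandmarkNetConfig) -> nn.Tensor:
    """Loss on the NHWC head output; gt arrays are channels-first."""
    k = cfg.n_cm
    target = np.concatenate([gt_cm, gt_paf[:, None]], axis=1).transpose(0, 2, 3, 1)
    wts = np.full(k + 1, 1.0 / k)
    wts[k] = cfg.paf_weight  # CM channels averaged, PAF weighted alpha/beta
    return nn.weighted_sum_squares(out, target.astype(out.v.dtype), wts)


def landmark_loss(
    pred_cm: np.ndarray,
    pred_paf: np.ndarray,
    gt_cm: np.ndarray,
    gt_paf: np.ndarray,
    cfg: LandmarkNetConfig,
) -> float:
    """Channel-averaged squared CM error plus weighted squared PAF error."""
    pred_cm = np.asarray(pred_cm, dtype=np.float64)
    pred_paf = np.asarray(pred_paf, dtype=np.float64)
    gt_cm = np.asarray(gt_cm, dtype=np.float64)
    gt_paf = np.asarray(gt_paf, dtype=np.float64)
    if pred_cm.ndim == 3:
        pred_cm, gt_cm = pred_cm[None], gt_cm[None]
        pred_paf, gt_paf = pred_paf[None], gt_paf[None]
    if pred_cm.shape != gt_cm.shape or pred_cm.shape[1] != cfg.n_cm:
        raise ValueError("confidence-map shape mismatch")
    if pred_paf.shape != gt_paf.shape:
        raise ValueError("PAF shape mismatch")
    cm_term = (( pred_cm - gt_cm) ** 2).sum() / cfg.n_cm
    paf_term = cfg.paf_weight * ((pred_paf - gt_paf) ** 2).sum()
    return float(cm_term + paf_term) / pred_cm.shape[0]


def decode_landmarks(pred_cm: np.ndarray, crop_transform: FrameTransform) -> np.ndarray:
    """Per-channel argmax (row-major tie-break) mapped through the crop frame.

    A constant channel has no peak; its centroid is used instead and a
    warning is emitted.
    """
    cm = np.asarray(pred_cm, dtype=np.float64)
    pts = []
    h, w = cm.shape[1:]
    for k in range(cm.shape[0]):
        ch = cm[k]
        if np.ptp(ch) == 0:
            warnings.warn(f"constant confidence channel {k}: falling back to centroid")
            pts.append(((w - 1) / 2.0, (h - 1) / 2.0))
            continue
        idx = int(np.argmax(ch))
        pts.append((idx % w, idx // w))
    return crop_transform.apply(np.asarray(pts, dtype=float))


def train_landmarknet(dataset, cfg: LandmarkNetConfig, tcfg: nn.TrainConfig, val_set=None):
    """Train on (crop256, gt confidence maps, gt paf) triples.

    Training crops are built from ground-truth centers; at inference time
    the pipeline crops around predicted centers instead — the random
    translation augmentation used upstream is what bridges that gap.
    """
    data = list(dataset)
    if not data:
        raise ValueError("empty dataset")
    if val_set is None:
        cut = max(1, int(0.8 * len(data)))
        data, val_set = data[:cut], data[cut:] or data[-1:]
    model = build_landmarknet(cfg)

    def loss_fn(m: LandmarkNet, batch):
        x = np.stack([b[0] for b in batch]).astype(np.float32)
        gt_cm = np.stack([b[1] for b in batch]).astype(np.float32)
        gt_paf = np.stack([b[2] for b in batch]).astype(np.float32)
        return _landmark_loss_t(m.forward(x), gt_cm, gt_paf, m.cfg)

    return nn.fit(model, data, list(val_set), tcfg, loss_fn)
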
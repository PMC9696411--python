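"""Center detector: a U-shaped heatmap network with widened kernels.

Maps a 1x512x512 preprocessed radiograph to 6 confidence maps at 64x64
(one per center, L1..L5 + S1), with an intermediate single-channel branch
that pre-predicts the L5 center map and is concatenated back into the trunk
before the final head — L5 is the easiest, brightest body, and anchoring
the trunk on it stabilizes the other five channels.

Two design points carry the detection behavior:

* **wide kernels** — two 13x13 convolutions sit at the bottleneck.  At the
  heatmap scale neighboring centers are only ~7 px apart, so a 7-px kernel
  barely sees one neighbor; 13 px spans about two inter-center gaps and
  lets the net place a center from its neighbors when the body itself is
  occluded;
* **pre-activation blocks** — every convolutional unit after the stem is
  ordered instance-norm -> ReLU -> conv.

Training: squared-error on both heads, ``L = ||C5_hat - C5_bar||^2 +
(1/6) sum_i ||Ci_hat - Ci||^2``, Adam with linear LR decay and early
stopping on validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["CenterNetConfig", "CenterNet", "build_centernet", "center_loss", "train_centernet"]


@dataclass(frozen=True)
class CenterNetConfig:
    base_channels: int = 8
    wide_kernel: int = 13
    n_wide: int = 2
    in_size: int = 512
    out_size: int = 64
    out_channels: int = 6
    norm: str = "instance"
    preactivation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_size != 8 * self.out_size:
            raise ValueError("in_size must be exactly 8x out_size")
        if self.wide_kernel % 2 == 0:
            raise ValueError("wide_kernel must be odd")
        if self.base_channels < 1 or self.n_wide < 1:
            raise ValueError("invalid channel/depth configuration")


class CenterNet:
    """Encoder-decoder from 512x512 input to (L5 branch, 6-channel) heatmaps."""

    def __init__(self, cfg: CenterNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        pre = cfg.preactivation
        norm = cfg.norm
        mk = lambda ci, co, k, s=1, preact=pre: nn.ConvLayer(
            ci, co, k, stride=s, rng=rng, preact=preact, norm=norm
        )
        self.stem = mk(1, c, 3, s=2, preact=False)  # 512 -> 256
        self.e2 = mk(c, 2 * c, 3, s=2)  # -> 128
        self.e3 = mk(2 * c, 2 * c, 3, s=2)  # -> 64 (skip)
        self.e4 = mk(2 * c, 2 * c, 3, s=2)  # -> 32
        self.wide = [mk(2 * c, 2 * c, cfg.wide_kernel) for _ in range(cfg.n_wide)]
        self.d1 = mk(4 * c, 2 * c, 3)  # after skip concat at 64
        self.branch = mk(2 * c, 1, 3)  # intermediate L5 map
        self.d2 = mk(2 * c + 1, 2 * c, 3)
        self.head = mk(2 * c, cfg.out_channels, 1)

    def layers(self):
        return [self.stem, self.e2, self.e3, self.e4, *self.wide, self.d1, self.branch, self.d2, self.head]

    def params(self):
        return [p for layer in self.layers() for p in layer.params()]

    def n_params(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def forward(self, x: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        """x: (N, 1, 512, 512) -> NHWC tensors (N,64,64,1) and (N,64,64,6)."""
        t = nn.Tensor(np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1))
        f = self.stem(t)
        f = self.e2(f)
        skip = self.e3(f)
        f = self.e4(skip)
        for layer in self.wide:
            f = layer(f)
        f = nn.upsample2x(f)
        f = self.d1(nn.concat([f, skip]))
        cbar5 = self.branch(f)
        f = self.d2(nn.concat([f, cbar5]))
        cmaps = self.head(f)
        return cbar5, cmaps

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference: (N, 6, 64, 64) heatmaps, clipped to [0, 1]."""
        _, cmaps = self.forward(x)
        return np.clip(cmaps.v.transpose(0, 3, 1, 2), 0.0, 1.0)


def build_centernet(cfg: CenterNetConfig) -> CenterNet:
    return CenterNet(cfg)


def _center_loss_t(cbar5: nn.Tensor, cmaps: nn.Tensor, gt5: np.ndarray, gt: np.ndarray) -> nn.Tensor:
    """Loss on NHWC tensors; gt5 is (N,64,64,1), gt (N,64,64,6)."""
    lpre = nn.sum_squares(cbar5, gt5)
    lfinal = nn.scale(nn.sum_squares(cmaps, gt), 1.0 / gt.shape[-1])
    return nn.add(lpre, lfinal)


def center_loss(c_hat: np.ndarray, c_bar5: np.ndarray, c_pred: np.ndarray) -> float:
    """Scalar training loss from ground truth and the two predicted heads.

    ``c_hat`` is the 6-channel ground-truth stack (its channel 4, counting
    from 0, is the L5 target for the intermediate branch); ``c_bar5`` the
    branch prediction (1 channel); ``c_pred`` the final 6-channel
    prediction.  Accepts (K,H,W) or batched (N,K,H,W) arrays.
    """
    c_hat = np.asarray(c_hat, dtype=np.float64)
    c_bar5 = np.asarray(c_bar5, dtype=np.float64)
    c_pred = np.asarray(c_pred, dtype=np.float64)
    if c_hat.ndim == 3:
        c_hat, c_bar5, c_pred = c_hat[None], c_bar5[None], c_pred[None]
    if c_pred.shape != c_hat.shape or c_bar5.shape[2:] != c_hat.shape[2:]:
        raise ValueError("shape mismatch between prediction and ground truth")
    to_nhwc = lambda a: a.transpose(0, 2, 3, 1)
    loss = _center_loss_t(
        nn.Tensor(to_nhwc(c_bar5)),
        nn.Tensor(to_nhwc(c_pred)),
        to_nhwc(c_hat[:, 4:5]),
        to_nhwc(c_hat),
    )
    return float(loss.v)


def train_centernet(dataset, cfg: CenterNetConfig, tcfg: nn.TrainConfig, val_set=None):
    """Train on (image512, 6-channel target stack) pairs.

    ``dataset``/``val_set`` are sequences of ``(img, gt)`` with ``img``
    shaped (1, 512, 512) (already preprocessed and normalized) and ``gt``
    shaped (6, 64, 64).  If ``val_set`` is None the last 20% of ``dataset``
    is held out for validation.
    """
    data = list(dataset)
    if not data:
        raise ValueError("empty dataset")
    if val_set is None:
        cut = max(1, int(0.8 * len(data)))
        data, val_set = data[:cut], data[cut:] or data[-1:]
    model = build_centernet(cfg)

    def loss_fn(m: CenterNet, batch):
        x = np.stack([b[0] for b in batch]).astype(np.float32)
        gt = np.stack([b[1] for b in batch]).astype(np.float32).transpose(0, 2, 3, 1)
        cbar5, cmaps = m.forward(x)
        return _center_loss_t(cbar5, cmaps, gt[..., 4:5], gt)

    return nn.fit(model, data, list(val_set), tcfg, loss_fn)
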
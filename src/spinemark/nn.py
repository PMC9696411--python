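"""Minimal CPU tensor framework for the detection networks.

A small reverse-mode tape over numpy arrays, with exactly the operations
the two detectors need: 2-D convolution (decomposed into per-offset BLAS
matmuls on shifted views — much cheaper on CPU than an im2col copy for the
small channel counts used here), instance normalization, ReLU,
nearest-neighbor 2x up/downsampling, channel concatenation and
sum-of-squares losses, plus an Adam optimizer with linear learning-rate
decay and patience-based early stopping.

Activations are NHWC (channels last) float32 by default; convolution
kernels are (k, k, Cin, Cout).  Gradients are exact (validated against
finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "backward",
    "conv2d",
    "instance_norm",
    "relu",
    "upsample2x",
    "avgpool2x",
    "concat",
    "add",
    "sum_squares",
    "scale",
    "ConvLayer",
    "Adam",
    "TrainConfig",
    "fit",
]


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("v", "g", "parents", "bwd", "requires_grad")

    def __init__(self, value, parents=(), bwd=None, requires_grad=False):
        self.v = np.asarray(value)
        self.g = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.v.shape


class Parameter(Tensor):
    def __init__(self, value):
        super().__init__(np.asarray(value), requires_grad=True)


def backward(loss: Tensor) -> None:
    """Reverse-mode sweep seeding d(loss)/d(loss) = 1."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    for node in order:
        node.g = None
    loss.g = np.ones_like(loss.v)
    for node in reversed(order):
        if node.bwd is not None and node.g is not None:
            node.bwd(node.g)


def _accum(node: Tensor, grad: np.ndarray) -> None:
    if not node.requires_grad:
        return
    if node.g is None:
        if grad.dtype == node.v.dtype and grad.flags["OWNDATA"]:
            node.g = grad  # fresh per-op buffer; safe to take ownership
        else:
            node.g = grad.astype(node.v.dtype)
    else:
        node.g += grad


# ---------------------------------------------------------------------------
# convolution


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int | None = None) -> Tensor:
    """Cross-correlation on NHWC input with a (k, k, Cin, Cout) kernel.

    'Same'-style padding ``(k-1)//2`` by default.  Computed as a sum over
    the k*k kernel offsets of shifted-view matmuls.
    """
    k = w.v.shape[0]
    if w.v.shape[1] != k:
        raise ValueError("square kernels only")
    if pad is None:
        pad = (k - 1) // 2
    n, h, wd, cin = x.v.shape
    cout = w.v.shape[3]
    xp = np.pad(x.v, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.v
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    out = np.zeros((n, ho, wo, cout), dtype=x.v.dtype)
    if b is not None:
        out += b.v
    yspan = (ho - 1) * stride + 1
    xspan = (wo - 1) * stride + 1
    for dy in range(k):
        for dx in range(k):
            sl = xp[:, dy : dy + yspan : stride, dx : dx + xspan : stride, :]
            out += sl @ w.v[dy, dx]
    parents = (x, w) if b is None else (x, w, b)
    node = Tensor(out, parents=parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 1, 2)))
        gm = g.reshape(-1, cout)
        if w.requires_grad:
            dw = np.empty_like(w.v)
            for dy in range(k):
                for dx in range(k):
                    sl = xp[:, dy : dy + yspan : stride, dx : dx + xspan : stride, :]
                    dw[dy, dx] = sl.reshape(-1, cin).T @ gm
            _accum(w, dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for dy in range(k):
                for dx in range(k):
                    dxp[:, dy : dy + yspan : stride, dx : dx + xspan : stride, :] += (
                        g @ w.v[dy, dx].T
                    )
            _accum(x, dxp[:, pad : pad + h, pad : pad + wd, :] if pad else dxp)

    node.bwd = bwd
    return node


# ---------------------------------------------------------------------------
# pointwise / structural ops


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    v = x.v
    mu = v.mean(axis=(1, 2), keepdims=True)
    var = v.var(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (v - mu) * inv
    node = Tensor(xhat * gamma.v + beta.v, parents=(x, gamma, beta))

    def bwd(g):
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 1, 2)))
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dxhat = g * gamma.v
            dx = (
                dxhat
                - dxhat.mean(axis=(1, 2), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
            ) * inv
            _accum(x, dx)

    node.bwd = bwd
    return node


def relu(x: Tensor) -> Tensor:
    mask = x.v > 0
    node = Tensor(np.where(mask, x.v, 0), parents=(x,))
    node.bwd = lambda g: _accum(x, g * mask)
    return node


def upsample2x(x: Tensor) -> Tensor:
    node = Tensor(x.v.repeat(2, axis=1).repeat(2, axis=2), parents=(x,))

    def bwd(g):
        n, h, w, c = g.shape
        _accum(x, g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)))

    node.bwd = bwd
    return node


def avgpool2x(x: Tensor) -> Tensor:
    n, h, w, c = x.v.shape
    v = x.v.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    node = Tensor(v, parents=(x,))

    def bwd(g):
        _accum(x, g.repeat(2, axis=1).repeat(2, axis=2) * 0.25)

    node.bwd = bwd
    return node


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    node = Tensor(np.concatenate([t.v for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.v.shape[axis] for t in tensors]

    def bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            _accum(t, g[tuple(sl)])
            start += s

    node.bwd = bwd
    return node


def add(a: Tensor, b: Tensor) -> Tensor:
    node = Tensor(a.v + b.v, parents=(a, b))

    def bwd(g):
        _accum(a, g)
        _accum(b, g.copy())  # no buffer sharing between the two parents

    node.bwd = bwd
    return node


def scale(x: Tensor, k: float) -> Tensor:
    node = Tensor(x.v * k, parents=(x,))
    node.bwd = lambda g: _accum(x, g * k)
    return node


def sum_squares(pred: Tensor, target: np.ndarray) -> Tensor:
    """||pred - target||^2 summed over all elements, averaged over the batch."""
    diff = pred.v - target
    n = pred.v.shape[0]
    node = Tensor(np.asarray(float((diff**2).sum()) / n), parents=(pred,))
    node.bwd = lambda g: _accum(pred, (2.0 / n) * float(g) * diff)
    return node


def weighted_sum_squares(pred: Tensor, target: np.ndarray, channel_weights: np.ndarray) -> Tensor:
    """Per-channel weighted squared error, channels last, batch-averaged."""
    wts = np.asarray(channel_weights, dtype=pred.v.dtype).reshape(1, 1, 1, -1)
    diff = pred.v - target
    n = pred.v.shape[0]
    node = Tensor(np.asarray(float((wts * diff**2).sum()) / n), parents=(pred,))
    node.bwd = lambda g: _accum(pred, (2.0 / n) * float(g) * wts * diff)
    return node


# ---------------------------------------------------------------------------
# layers


class ConvLayer:
    """Conv with optional pre-activation (instance norm -> ReLU -> conv)."""

    def __init__(self, cin, cout, k, stride=1, rng=None, preact=True, norm="instance", dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0, np.sqrt(2.0 / fan_in), (k, k, cin, cout))
        self.w = Parameter(w.astype(dtype))
        self.b = Parameter(np.zeros(cout, dtype=dtype))
        self.kernel = k
        self.stride = stride
        self.preact = preact
        self.norm = norm if preact else "none"
        if self.norm == "instance":
            self.gamma = Parameter(np.ones(cin, dtype=dtype))
            self.beta = Parameter(np.zeros(cin, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        if self.preact:
            if self.norm == "instance":
                x = instance_norm(x, self.gamma, self.beta)
            x = relu(x)
        return conv2d(x, self.w, self.b, stride=self.stride)

    def params(self):
        ps = [self.w, self.b]
        if self.norm == "instance":
            ps += [self.gamma, self.beta]
        return ps


# ---------------------------------------------------------------------------
# optimization


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.s = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, s in zip(self.params, self.m, self.s):
            if p.g is None:
                continue
            g = p.g
            m *= b1
            m += (1 - b1) * g
            s *= b2
            s += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            shat = s / (1 - b2**self.t)
            p.v -= self.lr * mhat / (np.sqrt(shat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.g = None


@dataclass
class TrainConfig:
    """Optimization protocol: Adam, linear LR decay, patience early stop."""

    lr: float = 1e-4
    batch: int = 16
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def fit(model, train_set, val_set, tcfg: TrainConfig, loss_fn):
    """Generic mini-batch training loop shared by both detector stages.

    ``train_set``/``val_set`` are lists of samples; ``loss_fn(model, batch)``
    returns the loss Tensor.  The learning rate decays linearly to 0 over
    ``max_epochs``; training stops early once the validation loss has not
    improved for ``patience`` epochs; the best-validation weights are
    restored before returning.

    Returns ``(model, history)`` where history is a dict of per-epoch
    train/val losses.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params(), lr=tcfg.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = [p.v.copy() for p in model.params()]
    since_best = 0
    n = len(train_set)
    for epoch in range(tcfg.max_epochs):
        opt.lr = tcfg.lr * (1.0 - epoch / tcfg.max_epochs)
        order = rng.permutation(n)
        tot, nb = 0.0, 0
        for start in range(0, n, tcfg.batch):
            batch = [train_set[i] for i in order[start : start + tcfg.batch]]
            opt.zero_grad()
            loss = loss_fn(model, batch)
            backward(loss)
            opt.step()
            tot += float(loss.v)
            nb += 1
        history["train_loss"].append(tot / nb)

        vtot, vb = 0.0, 0
        for start in range(0, len(val_set), tcfg.batch):
            batch = val_set[start : start + tcfg.batch]
            vtot += float(loss_fn(model, batch).v)
            vb += 1
        val = vtot / max(vb, 1)
        history["val_loss"].append(val)

        if val < best_val - 1e-12:
            best_val = val
            best_state = [p.v.copy() for p in model.params()]
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                break
    for p, v in zip(model.params(), best_state):
        p.v = v
    return model, history
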
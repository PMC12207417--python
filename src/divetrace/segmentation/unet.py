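"""A small U-Net implemented directly on NumPy.

Encoder-decoder segmentation network with skip connections: per level two
3x3 same-padding convolutions + ReLU, 2x2 max-pooling down and nearest-
neighbour upsampling up, channel-concatenated skips, and a final 1x1
convolution to per-class logits. Trained by minimizing pixel-wise weighted
categorical cross-entropy with Adam; the rare whale class is up-weighted
against the others by default.

Convolutions use an im2col/matmul formulation; gradients are written out
explicitly layer by layer. This keeps the network small and dependency-free
and is entirely adequate for the reduced training scales this package runs
at (tiles of 64-256 px, a few thousand images).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..classes import DEFAULT_CLASS_WEIGHTS, N_CLASSES


@dataclass
class UNetConfig:
    """Architecture + training hyperparameters.

    ``bridge_width`` is the filter count of the bottleneck block; ``None``
    derives it as ``base_filters * 2**levels``. Defaults describe the
    full-scale configuration (4 levels, 256-px tiles, 100 epochs, batch 20,
    whale weight 10:1); tests and the synthetic demo use reduced configs.
    """

    levels: int = 4
    base_filters: int = 16
    bridge_width: int | None = None
    n_classes: int = N_CLASSES
    tile_size: int = 256
    class_weights: tuple = DEFAULT_CLASS_WEIGHTS
    epochs: int = 100
    batch_size: int = 20
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.tile_size % (2 ** self.levels) != 0:
            raise ValueError(
                f"tile_size {self.tile_size} must be divisible by "
                f"2**levels = {2 ** self.levels}"
            )
        if len(self.class_weights) != self.n_classes:
            raise ValueError("class_weights length must equal n_classes")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be positive")

    @property
    def bridge_filters(self) -> int:
        return (
            self.bridge_width
            if self.bridge_width is not None
            else self.base_filters * 2 ** self.levels
        )


# ---------------------------------------------------------------------------
# Layer primitives (forward + backward)
# ---------------------------------------------------------------------------


def conv_forward(x, W, b):
    """3x3 same conv. x: (N,H,Wd,Cin); W: (3,3,Cin,Cout); returns y, cache."""
    N, H, Wd, Cin = x.shape
    Cout = W.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))     # (N,H,Wd,Cin,3,3)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        N * H * Wd, 9 * Cin
    )
    Wm = W.reshape(9 * Cin, Cout)
    y = (cols @ Wm + b).reshape(N, H, Wd, Cout)
    return y, (cols, Wm, x.shape)


def conv_backward(dy, W, cache):
    cols, Wm, xshape = cache
    N, H, Wd, Cin = xshape
    Cout = W.shape[-1]
    dy2 = dy.reshape(-1, Cout)
    dW = (cols.T @ dy2).reshape(W.shape)
    db = dy2.sum(axis=0)
    dcols = (dy2 @ Wm.T).reshape(N, H, Wd, 3, 3, Cin)
    dxp = np.zeros((N, H + 2, Wd + 2, Cin), dtype=dy.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, i:i + H, j:j + Wd, :] += dcols[:, :, :, i, j, :]
    return dxp[:, 1:-1, 1:-1, :], dW, db


def conv1x1_forward(x, W, b):
    """1x1 conv. W: (Cin, Cout)."""
    y = x @ W + b
    return y, x


def conv1x1_backward(dy, W, x):
    dW = np.tensordot(x, dy, axes=([0, 1, 2], [0, 1, 2]))
    db = dy.sum(axis=(0, 1, 2))
    dx = dy @ W.T
    return dx, dW, db


def relu_forward(x):
    y = np.maximum(x, 0.0)
    return y, y


def relu_backward(dy, y):
    return dy * (y > 0)


def maxpool_forward(x):
    """2x2 max-pooling, stride 2; H and W must be even."""
    N, H, Wd, C = x.shape
    xr = x.reshape(N, H // 2, 2, Wd // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    xr = np.ascontiguousarray(xr).reshape(N, H // 2, Wd // 2, C, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool_backward(dy, cache):
    idx, xshape = cache
    N, H, Wd, C = xshape
    d = np.zeros((N, H // 2, Wd // 2, C, 4), dtype=dy.dtype)
    np.put_along_axis(d, idx[..., None], dy[..., None], axis=-1)
    d = d.reshape(N, H // 2, Wd // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return np.ascontiguousarray(d).reshape(N, H, Wd, C)


def upsample_forward(x):
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample_backward(dy):
    N, H, Wd, C = dy.shape
    return dy.reshape(N, H // 2, 2, Wd // 2, 2, C).sum(axis=(2, 4))


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_pixel_loss(probs, labels, class_weights, valid=None):
    """Per-pixel weighted cross-entropy contributions (not normalized).

    Returns an array shaped like ``labels``; padding/ignored pixels
    (``valid`` False) contribute zero. Useful as an oracle: doubling a
    class's weight exactly doubles that class's pixels' contributions.
    """
    w = np.asarray(class_weights, dtype=probs.dtype)
    p_true = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
    contrib = -w[labels] * np.log(np.maximum(p_true, 1e-12))
    if valid is not None:
        contrib = contrib * valid
    return contrib


def loss_and_grad(logits, labels, class_weights, valid=None):
    """Weighted categorical cross-entropy, normalized by the total pixel
    weight; returns (scalar loss, dLoss/dlogits)."""
    probs = softmax(logits)
    w = np.asarray(class_weights, dtype=logits.dtype)
    wpix = w[labels]
    if valid is not None:
        wpix = wpix * valid
    norm = max(float(wpix.sum()), 1e-12)
    contrib = weighted_pixel_loss(probs, labels, class_weights, valid)
    loss = float(contrib.sum()) / norm
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    dlogits = wpix[..., None] * (probs - onehot) / norm
    return loss, dlogits


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


def _channel_plan(cfg: UNetConfig) -> dict:
    """Per-layer (Cin, Cout) pairs; the independent parameter-count oracle
    in the tests recomputes these from first principles."""
    F = cfg.base_filters
    plan = {}
    cin = 1
    for i in range(cfg.levels):
        f = F * 2 ** i
        plan[f"enc{i}a"] = (cin, f)
        plan[f"enc{i}b"] = (f, f)
        cin = f
    B = cfg.bridge_filters
    plan["bridgea"] = (cin, B)
    plan["bridgeb"] = (B, B)
    up_in = B
    for i in reversed(range(cfg.levels)):
        f = F * 2 ** i
        plan[f"dec{i}a"] = (up_in + f, f)   # upsampled + skip concat
        plan[f"dec{i}b"] = (f, f)
        up_in = f
    plan["out"] = (up_in, cfg.n_classes)
    return plan


def parameter_count(cfg: UNetConfig) -> int:
    plan = _channel_plan(cfg)
    total = 0
    for name, (cin, cout) in plan.items():
        k = 1 if name == "out" else 9
        total += k * cin * cout + cout
    return total


class NumpyUNet:
    """Trainable U-Net instance. Weights live in ``self.params`` keyed by
    layer name ('W'/'b' suffix); Adam state in ``self.opt``."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.plan = _channel_plan(config)
        rng = np.random.default_rng(config.seed)
        self.params = {}
        for name, (cin, cout) in self.plan.items():
            if name == "out":
                fan_in = cin
                self.params[name + "_W"] = (
                    rng.normal(0.0, np.sqrt(2.0 / fan_in), (cin, cout))
                ).astype(np.float32)
            else:
                fan_in = 9 * cin
                self.params[name + "_W"] = (
                    rng.normal(0.0, np.sqrt(2.0 / fan_in), (3, 3, cin, cout))
                ).astype(np.float32)
            self.params[name + "_b"] = np.zeros(cout, dtype=np.float32)
        self.opt = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()}
        self.opt_t = 0

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ----------------------------------------------------------

    def _conv_block(self, x, name, caches):
        p = self.params
        y, c1 = conv_forward(x, p[f"{name}a_W"], p[f"{name}a_b"])
        y, r1 = relu_forward(y)
        y, c2 = conv_forward(y, p[f"{name}b_W"], p[f"{name}b_b"])
        y, r2 = relu_forward(y)
        caches[name] = (c1, r1, c2, r2)
        return y

    def forward(self, x, want_cache: bool = False):
        """x: (N,H,W) or (N,H,W,1) float32 in [0,1], NaN-free. Returns
        logits (N,H,W,K) and, optionally, the backward cache."""
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(np.float32, copy=False)
        L = self.config.levels
        caches: dict = {}
        skips = []
        h = x
        for i in range(L):
            h = self._conv_block(h, f"enc{i}", caches)
            skips.append(h)
            h, pc = maxpool_forward(h)
            caches[f"pool{i}"] = pc
        h = self._conv_block(h, "bridge", caches)
        for i in reversed(range(L)):
            h = upsample_forward(h)
            caches[f"cat{i}"] = (h.shape[-1], skips[i].shape[-1])
            h = np.concatenate([h, skips[i]], axis=-1)
            h = self._conv_block(h, f"dec{i}", caches)
        logits, oc = conv1x1_forward(h, self.params["out_W"], self.params["out_b"])
        caches["out"] = oc
        return (logits, caches) if want_cache else logits

    def predict_proba(self, x):
        return softmax(self.forward(x))

    # -- backward ---------------------------------------------------------

    def _conv_block_backward(self, dy, name, caches, grads):
        p = self.params
        c1, r1, c2, r2 = caches[name]
        dy = relu_backward(dy, r2)
        dy, dW2, db2 = conv_backward(dy, p[f"{name}b_W"], c2)
        grads[f"{name}b_W"] = dW2
        grads[f"{name}b_b"] = db2
        dy = relu_backward(dy, r1)
        dy, dW1, db1 = conv_backward(dy, p[f"{name}a_W"], c1)
        grads[f"{name}a_W"] = dW1
        grads[f"{name}a_b"] = db1
        return dy

    def backward(self, dlogits, caches):
        grads: dict = {}
        L = self.config.levels
        dh, dWo, dbo = conv1x1_backward(dlogits, self.params["out_W"], caches["out"])
        grads["out_W"] = dWo
        grads["out_b"] = dbo
        dskips = {}
        for i in range(L):
            dh = self._conv_block_backward(dh, f"dec{i}", caches, grads)
            n_up, n_skip = caches[f"cat{i}"]
            dskips[i] = dh[..., n_up:]
            dh = upsample_backward(dh[..., :n_up])
        dh = self._conv_block_backward(dh, "bridge", caches, grads)
        for i in reversed(range(L)):
            dh = maxpool_backward(dh, caches[f"pool{i}"])
            dh = dh + dskips[i]
            dh = self._conv_block_backward(dh, f"enc{i}", caches, grads)
        return grads

    # -- optimization -----------------------------------------------------

    def adam_step(self, grads, lr=None, beta1=0.9, beta2=0.999, eps=1e-8):
        lr = self.config.learning_rate if lr is None else lr
        self.opt_t += 1
        t = self.opt_t
        for k, g in grads.items():
            m, v = self.opt[k]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self.opt[k] = (m, v)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    def train_step(self, x, labels, valid=None):
        """One optimizer step on a batch; returns the batch loss."""
        logits, caches = self.forward(x, want_cache=True)
        loss, dlogits = loss_and_grad(
            logits, labels, self.config.class_weights, valid
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: non-finite loss {loss!r} at step {self.opt_t + 1}"
            )
        grads = self.backward(dlogits, caches)
        self.adam_step(grads)
        return loss

    def evaluate_loss(self, x, labels, valid=None, batch_size: int | None = None):
        """Mean weighted loss over a dataset, without gradient work."""
        bs = batch_size or self.config.batch_size
        total, weight = 0.0, 0.0
        for lo in range(0, x.shape[0], bs):
            xb = x[lo:lo + bs]
            yb = labels[lo:lo + bs]
            vb = valid[lo:lo + bs] if valid is not None else None
            logits = self.forward(xb)
            loss, _ = loss_and_grad(logits, yb, self.config.class_weights, vb)
            total += loss * xb.shape[0]
            weight += xb.shape[0]
        return total / max(weight, 1.0)

    # -- checkpointing ----------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()
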
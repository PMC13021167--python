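"""Minimal seeded neural-network engine on numpy.

Provides exactly what the grading models need: 3x3/1x1 same-padding
convolutions, ReLU, 2x2 max pooling, nearest-neighbor upsampling, channel
concatenation, dense heads, Adam, and logit-space losses (binary
cross-entropy, soft Dice, sparse categorical cross-entropy).  Tensors are
NHWC.  Every weight draw comes from a generator seeded at model
construction, so initialization is bit-reproducible; the backward pass is
written by hand layer by layer.

Convolutions are evaluated as nine shifted matrix products (one per kernel
tap), which keeps both directions as plain BLAS calls without an im2col
buffer.
"""

from __future__ import annotations

import numpy as np


def _init_weights(shape, fan_in: int, fan_out: int, scheme: str, rng: np.random.Generator):
    if scheme == "he_normal":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    if scheme == "xavier_uniform":
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)
    raise ValueError(f"unknown init scheme {scheme!r}")


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)


class Conv2D:
    """k x k same-padding convolution with optional fused ReLU."""

    def __init__(self, cin, cout, ksize=3, init="he_normal", rng=None, relu=True):
        self.k = ksize
        self.relu = relu
        fan_in, fan_out = ksize * ksize * cin, ksize * ksize * cout
        self.w = Param(_init_weights((ksize, ksize, cin, cout), fan_in, fan_out, init, rng))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w_, cin = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        out = np.broadcast_to(self.b.v, (n, h, w_, self.b.v.size)).copy()
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w_, :] @ self.w.v[i, j]
        self._xp, self._shape = xp, (n, h, w_, cin)
        if self.relu:
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = np.where(self._mask, dy, 0.0)
        k, p = self.k, self.k // 2
        n, h, w_, cin = self._shape
        dxp = np.zeros_like(self._xp)
        dy2 = dy.reshape(-1, dy.shape[-1])
        for i in range(k):
            for j in range(k):
                sl = self._xp[:, i : i + h, j : j + w_, :]
                self.w.g[i, j] += sl.reshape(-1, cin).T @ dy2
                dxp[:, i : i + h, j : j + w_, :] += dy @ self.w.v[i, j].T
        self.b.g += dy2.sum(axis=0)
        self._xp = None
        return dxp[:, p : p + h, p : p + w_, :] if p else dxp


class MaxPool2:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # split gradient evenly across ties for determinism
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        dxr = self._mask * dy[:, :, None, :, None, :]
        self._mask = None
        return dxr.reshape(n, h2 * 2, w2 * 2, c)


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dense:
    def __init__(self, nin, nout, init="xavier_uniform", rng=None):
        self.w = Param(_init_weights((nin, nout), nin, nout, init, rng))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.v + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.g += self._x.T @ dy
        self.b.g += dy.sum(axis=0)
        self._x = None
        return dy @ self.w.v.T


class GlobalAvgPool:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


# ---------------------------------------------------------------------------
# Losses (logit space, returning (loss, dlogits))
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    zs = z - z.max(axis=-1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=-1, keepdims=True)


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    y = np.asarray(y, dtype=np.float64).reshape(z.shape)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / z.size
    return float(loss), dz


def dice_with_logits(z: np.ndarray, y: np.ndarray, eps: float = 1.0):
    """Soft Dice loss over the whole batch (1 - overlap of probabilities)."""
    y = np.asarray(y, dtype=np.float64).reshape(z.shape)
    p = sigmoid(z)
    num = 2.0 * float((p * y).sum()) + eps
    den = float(p.sum() + y.sum()) + eps
    loss = 1.0 - num / den
    dp = -(2.0 * y * den - num) / (den * den)
    dz = dp * p * (1.0 - p)
    return float(loss), dz


def sparse_ce_with_logits(z: np.ndarray, y: np.ndarray):
    """Softmax cross-entropy with integer labels on the trailing class axis."""
    y = np.asarray(y, dtype=np.int64)
    p = softmax(z)
    flat_p = p.reshape(-1, z.shape[-1])
    flat_y = y.reshape(-1)
    n = flat_y.size
    picked = flat_p[np.arange(n), flat_y]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    dflat = flat_p.copy()
    dflat[np.arange(n), flat_y] -= 1.0
    return loss, (dflat / n).reshape(z.shape)


LOSSES = {
    "binary_cross_entropy": bce_with_logits,
    "dice": dice_with_logits,
    "sparse_categorical_cross_entropy": sparse_ce_with_logits,
}


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.vv = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.vv):
            m *= self.b1
            m += (1 - self.b1) * p.g
            v *= self.b2
            v += (1 - self.b2) * p.g * p.g
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class Network:
    """Common surface: forward to logits, backward, params, predict."""

    final_activation = "sigmoid"

    def params(self):
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dz: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights):
            p.v[...] = w

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        outs = []
        for i in range(0, x.shape[0], batch_size):
            z = self.forward(x[i : i + batch_size])
            if self.final_activation == "sigmoid":
                outs.append(sigmoid(z))
            else:
                outs.append(softmax(z))
        out = np.concatenate(outs, axis=0)
        return out[0] if single else out


class UNet(Network):
    """Symmetric encoder-decoder with skip connections.

    ``n_contraction`` blocks of two 3x3 convolutions each, filter count
    doubling from ``base_filters``; all but the last block downsample 2x.
    The mirrored expansion path upsamples, concatenates the matching skip
    and convolves twice; a 1x1 head emits ``out_channels`` logits
    (sigmoid for binary masks, softmax over classes for segmentation).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int = 1,
        n_contraction: int = 4,
        base_filters: int = 16,
        init: str = "he_normal",
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        L = n_contraction
        self.n_contraction = L
        self.enc, self.pools, self.ups, self.dec = [], [], [], []
        cin = in_channels
        for i in range(L):
            f = base_filters * 2 ** i
            self.enc.append(
                [Conv2D(cin, f, 3, init, rng), Conv2D(f, f, 3, init, rng)]
            )
            cin = f
            if i < L - 1:
                self.pools.append(MaxPool2())
        for i in range(L - 2, -1, -1):
            f = base_filters * 2 ** i
            self.ups.append(Upsample2())
            self.dec.append(
                [Conv2D(cin + f, f, 3, init, rng), Conv2D(f, f, 3, init, rng)]
            )
            cin = f
        self.head = Conv2D(cin, out_channels, 1, init, rng, relu=False)
        self.final_activation = "sigmoid" if out_channels == 1 else "softmax"

    def params(self):
        ps = []
        for blk in self.enc + self.dec:
            for c in blk:
                ps += c.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        L = self.n_contraction
        skips = []
        h = x
        for i in range(L - 1):
            h = self.enc[i][1].forward(self.enc[i][0].forward(h))
            skips.append(h)
            h = self.pools[i].forward(h)
        h = self.enc[L - 1][1].forward(self.enc[L - 1][0].forward(h))
        self._skip_ch = []
        for j in range(L - 1):
            skip = skips[L - 2 - j]
            h = self.ups[j].forward(h)
            self._skip_ch.append(h.shape[-1])
            h = np.concatenate([h, skip], axis=-1)
            h = self.dec[j][1].forward(self.dec[j][0].forward(h))
        return self.head.forward(h)

    def backward(self, dz: np.ndarray) -> np.ndarray:
        L = self.n_contraction
        dh = self.head.backward(dz)
        dskips = [None] * (L - 1)
        for j in range(L - 2, -1, -1):
            dh = self.dec[j][0].backward(self.dec[j][1].backward(dh))
            cut = self._skip_ch[j]
            dup, dskip = dh[..., :cut], dh[..., cut:]
            dskips[L - 2 - j] = dskip
            dh = self.ups[j].backward(dup)
        dh = self.enc[L - 1][0].backward(self.enc[L - 1][1].backward(dh))
        for i in range(L - 2, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc[i][0].backward(self.enc[i][1].backward(dh))
        return dh


class ClassifierCNN(Network):
    """Stacked conv/pool blocks, global average pooling, sigmoid unit."""

    def __init__(
        self,
        in_channels: int = 2,
        n_blocks: int = 4,
        base_filters: int = 16,
        init: str = "xavier_uniform",
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.convs, self.pools = [], []
        cin = in_channels
        for i in range(n_blocks):
            f = base_filters * 2 ** i
            self.convs.append(Conv2D(cin, f, 3, init, rng))
            self.pools.append(MaxPool2())
            cin = f
        self.gap = GlobalAvgPool()
        self.fc = Dense(cin, 1, init, rng)
        self.final_activation = "sigmoid"

    def params(self):
        ps = []
        for c in self.convs:
            ps += c.params()
        ps += self.fc.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, pool in zip(self.convs, self.pools):
            h = pool.forward(conv.forward(h))
        return self.fc.forward(self.gap.forward(h))

    def backward(self, dz: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(self.fc.backward(dz))
        for conv, pool in zip(reversed(self.convs), reversed(self.pools)):
            dh = conv.backward(pool.backward(dh))
        return dh
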
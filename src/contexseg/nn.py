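"""Minimal deterministic CNN building blocks in numpy.

A compact U-Net (encoder/decoder with skip connections, dropout before
each pooling, softmax head) with hand-written forward and backward
passes.  Backpropagation reaches the input image, which is what the
Integrated-Gradients saliency module differentiates through.  All
randomness flows through explicit ``numpy.random.Generator`` objects,
so identical seeds give bit-identical training runs on one CPU.

Array layout is (N, C, H, W).  Convolutions are 3x3, stride 1, zero
padded ("same"), implemented as nine shifted einsums, which is fast in
numpy at the image sizes this package trains on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _conv3x3(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """y[n,o] = sum_c W[o,c] * x[n,c] (3x3, zero-padded) + b[o]."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.empty((n, W.shape[0], h, w), dtype=x.dtype)
    y[:] = b[None, :, None, None]
    for di in range(3):
        for dj in range(3):
            y += np.einsum(
                "nchw,oc->nohw",
                xp[:, :, di:di + h, dj:dj + w],
                W[:, :, di, dj],
                optimize=True,
            )
    return y


def _conv3x3_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of ``_conv3x3``."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(W)
    for di in range(3):
        for dj in range(3):
            xs = xp[:, :, di:di + h, dj:dj + w]
            dW[:, :, di, dj] = np.einsum(
                "nohw,nchw->oc", dy, xs, optimize=True
            )
            dxp[:, :, di:di + h, dj:dj + w] += np.einsum(
                "nohw,oc->nchw", dy, W[:, :, di, dj], optimize=True
            )
    db = dy.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


class Conv3x3:
    """3x3 same-padding convolution with He-initialized weights."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _conv3x3(x, self.W, self.b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, dW, db = _conv3x3_backward(self._x, self.W, dy)
        self.gW += dW
        self.gb += db
        return dx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Conv1x1:
    """1x1 convolution used as the class-logit head."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, scale, size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (np.einsum("nchw,oc->nohw", x, self.W, optimize=True)
                + self.b[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW += np.einsum("nohw,nchw->oc", dy, self._x, optimize=True)
        self.gb += dy.sum(axis=(0, 2, 3))
        return np.einsum("nohw,oc->nchw", dy, self.W, optimize=True)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


def relu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns pooled array and argmax one-hot mask."""
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = r.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    onehot = np.zeros_like(flat)
    np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
    return y, onehot


def maxpool2_backward(dy: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    n, c, h2, w2, _ = onehot.shape
    dflat = onehot * dy[..., None]
    return (dflat.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2))


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over axis 1."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def class_balanced_ce(
    probs: np.ndarray, labels: np.ndarray, n_classes: int
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy per output class, averaged over classes.

    The per-class cross-entropy is averaged over the pixels of that
    class, then the mean over classes present in the batch is taken —
    so the dominant background class does not swamp the tissue classes.
    Returns the loss and its gradient with respect to the logits.
    """
    n, c, h, w = probs.shape
    eps = 1e-12
    onehot = np.zeros_like(probs)
    for k in range(n_classes):
        onehot[:, k][labels == k] = 1.0
    counts = onehot.sum(axis=(0, 2, 3))
    present = counts > 0
    n_present = int(present.sum())
    loss = 0.0
    weights = np.zeros((n, 1, h, w))
    for k in range(n_classes):
        if not present[k]:
            continue
        sel = labels == k
        loss += -np.log(probs[:, k][sel] + eps).mean()
        weights[:, 0][sel] = 1.0 / (counts[k] * n_present)
    loss /= n_present
    # d(loss)/d(logits) through softmax: (p - onehot) * per-pixel weight
    dlogits = (probs - onehot) * weights
    return float(loss), dlogits


@dataclass
class UNetSpec:
    """Architecture hyperparameters; H, W must be divisible by 2^depth."""

    in_channels: int = 1
    n_classes: int = 4
    depth: int = 2
    base_channels: int = 8
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


class UNet:
    """Small U-Net with dropout before each pooling layer.

    ``forward`` caches activations; ``backward`` propagates a logit
    gradient to parameter gradients and the input-image gradient.
    Dropout is applied only when a training RNG is passed.
    """

    def __init__(self, spec: UNetSpec, rng: np.random.Generator):
        self.spec = spec
        chans = [spec.base_channels * 2 ** i for i in range(spec.depth + 1)]
        self.enc: list[tuple[Conv3x3, Conv3x3]] = []
        c_in = spec.in_channels
        for c in chans[:-1]:
            self.enc.append((Conv3x3(c_in, c, rng), Conv3x3(c, c, rng)))
            c_in = c
        self.bott = (Conv3x3(c_in, chans[-1], rng),
                     Conv3x3(chans[-1], chans[-1], rng))
        self.dec: list[tuple[Conv3x3, Conv3x3]] = []
        c_up = chans[-1]
        for c in reversed(chans[:-1]):
            self.dec.append((Conv3x3(c_up + c, c, rng), Conv3x3(c, c, rng)))
            c_up = c
        self.head = Conv1x1(c_up, spec.n_classes, rng)
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        for pair in self.enc:
            yield from pair
        yield from self.bott
        for pair in self.dec:
            yield from pair
        yield self.head

    def params(self):
        for layer in self.layers():
            yield from layer.params()

    def zero_grad(self) -> None:
        for layer in self.layers():
            for _, g in layer.params():
                g[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers()
                for p, _ in layer.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers() for p, _ in layer.params()]
        if len(flat) != len(state):
            raise ValueError("state does not match the architecture")
        for p, s in zip(flat, state):
            p[...] = s

    # -- forward / backward -------------------------------------------------
    def forward(
        self, x: np.ndarray, train_rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Return logits (N, n_classes, H, W); caches for backward."""
        h, w = x.shape[2], x.shape[3]
        if h % 2 ** self.spec.depth or w % 2 ** self.spec.depth:
            raise ValueError(
                f"H and W must be divisible by {2 ** self.spec.depth}"
            )
        cache: dict = {"relu": [], "pool": [], "drop": [], "skip_c": []}
        rate = self.spec.dropout_rate
        out = x
        for conv1, conv2 in self.enc:
            out, m1 = relu(conv1.forward(out))
            out, m2 = relu(conv2.forward(out))
            cache["relu"].append((m1, m2))
            cache["skip_c"].append(out.shape[1])
            if train_rng is not None and rate > 0:
                keep = (train_rng.random(out.shape) >= rate) / (1 - rate)
            else:
                keep = None
            cache["drop"].append(keep)
            skip = out  # skip taken before dropout+pool
            cache.setdefault("skips", []).append(skip)
            if keep is not None:
                out = out * keep
            out, oh = maxpool2(out)
            cache["pool"].append(oh)
        out, mb1 = relu(self.bott[0].forward(out))
        out, mb2 = relu(self.bott[1].forward(out))
        cache["bott_relu"] = (mb1, mb2)
        for level, (conv1, conv2) in enumerate(self.dec):
            skip = cache["skips"][-(level + 1)]
            out = np.concatenate([skip, upsample2(out)], axis=1)
            out, m1 = relu(conv1.forward(out))
            out, m2 = relu(conv2.forward(out))
            cache["relu"].append((m1, m2))
        logits = self.head.forward(out)
        self._cache = cache
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate to parameters; returns d/d(input image)."""
        cache = self._cache
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * len(self.enc)
        n_dec = len(self.dec)
        for level in reversed(range(n_dec)):
            conv1, conv2 = self.dec[level]
            m1, m2 = cache["relu"][len(self.enc) + level]
            d = conv2.backward(d * m2)
            d = conv1.backward(d * m1)
            c_skip = cache["skip_c"][-(level + 1)]
            dskips[len(self.enc) - 1 - level] = d[:, :c_skip]
            d = upsample2_backward(d[:, c_skip:])
        mb1, mb2 = cache["bott_relu"]
        d = self.bott[1].backward(d * mb2)
        d = self.bott[0].backward(d * mb1)
        for level in reversed(range(len(self.enc))):
            conv1, conv2 = self.enc[level]
            d = maxpool2_backward(d, cache["pool"][level])
            keep = cache["drop"][level]
            if keep is not None:
                d = d * keep
            d = d + dskips[level]
            m1, m2 = cache["relu"][level]
            d = conv2.backward(d * m2)
            d = conv1.backward(d * m1)
        return d


class Adam:
    """Adam optimizer over a UNet's (param, grad) pairs."""

    def __init__(self, net: UNet, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.net.params(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
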
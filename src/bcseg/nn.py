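"""Minimal CPU neural-network backbone for the segmentation model.

Implements exactly the pieces the five-level U-Net needs — 3×3 "same"
convolutions (im2col + BLAS matmul), batch normalization, ReLU, 2×2 max
pooling, 2×2 stride-2 transposed convolutions, a sigmoid head, the soft-Dice
training objective, and the Adam optimizer — with explicit forward/backward
passes in float32.  Layers own their parameters and gradient buffers; the
optimizer updates them in place.

Tensor layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2",
    "ConvTranspose2x2",
    "ConvBNReLU",
    "UNet2D",
    "Adam",
    "soft_dice_loss",
]

_EPS = 1e-5


class Layer:
    """Base class: parameters/gradients as name -> float32 array dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C*k*k, H*W) patch matrix for stride-1 same convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(b, c, k, k, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(view).reshape(b, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    b, c, h, w = xshape
    d = dcols.reshape(b, c, k, k, h, w)
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2D(Layer):
    """k×k stride-1 'same' convolution, He-normal initialization."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        std = np.sqrt(2.0 / (cin * k * k))
        self.params["w"] = rng.normal(0.0, std, (cout, cin * k * k)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        if train:
            self._cols, self._xshape = cols, x.shape
        y = np.matmul(self.params["w"][None], cols)  # (B, cout, H*W)
        y += self.params["b"][None, :, None]
        return y.reshape(b, self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = dy.shape
        dyf = dy.reshape(b, self.cout, h * w)
        self.grads["w"] += np.einsum("boi,bci->oc", dyf, self._cols, optimize=True)
        self.grads["b"] += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.params["w"].T[None], dyf)
        dx = _col2im(dcols, self._xshape, self.k, self.pad)
        self._cols = None
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, c: int, momentum: float = 0.9) -> None:
        super().__init__()
        self.momentum = momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        m1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        m2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - m1 / n - xhat * m2 / n) * inv[None, :, None, None]
        self._cache = None
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2×2 stride-2 max pooling (H, W must be even)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        v = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(b, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._xshape
        dv = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dv, self._idx[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(b, c, h, w)


class ConvTranspose2x2(Layer):
    """2×2 stride-2 transposed convolution: doubles H and W (no overlap)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.params["w"] = rng.normal(0.0, std, (cin, cout, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        if train:
            self._x = x
        t = np.tensordot(x, self.params["w"], axes=([1], [0]))  # (B,H,W,cout,2,2)
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(b, self.cout, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(b, self.cout, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (B,H,W,cout,2,2)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        self.grads["w"] += np.tensordot(self._x, dyb, axes=([0, 2, 3], [0, 1, 2]))
        dx = np.tensordot(dyb, self.params["w"], axes=([3, 4, 5], [1, 2, 3]))  # (B,H,W,cin)
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ConvBNReLU(Layer):
    """The basic block of the encoder/decoder: Conv -> BatchNorm -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = Conv2D(cin, cout, rng)
        self.bn = BatchNorm2D(cout)
        self.relu = ReLU()
        self.children = [self.conv, self.bn, self.relu]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.children:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.children):
            dy = layer.backward(dy)
        return dy


class UNet2D:
    """Encoder-decoder segmentation network with skip connections.

    `depth` resolution levels (depth-1 pool/upsample transitions); two
    Conv-BN-ReLU blocks per level; channel width doubles per level from
    `base_filters`; 1×1 convolution + sigmoid head producing a per-pixel
    probability map.
    """

    def __init__(self, in_channels: int = 3, base_filters: int = 32, depth: int = 5,
                 seed: int = 0) -> None:
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        ch = [base_filters * 2**i for i in range(depth)]
        self.enc: list[list[ConvBNReLU]] = []
        cin = in_channels
        for c in ch:
            self.enc.append([ConvBNReLU(cin, c, rng), ConvBNReLU(c, c, rng)])
            cin = c
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups: list[ConvTranspose2x2] = []
        self.dec: list[list[ConvBNReLU]] = []
        for lvl in range(depth - 2, -1, -1):
            self.ups.append(ConvTranspose2x2(ch[lvl + 1], ch[lvl], rng))
            self.dec.append([ConvBNReLU(2 * ch[lvl], ch[lvl], rng), ConvBNReLU(ch[lvl], ch[lvl], rng)])
        self.head = Conv2D(ch[0], 1, rng, k=1)
        # prior-matched head init: small weights and a negative bias keep the
        # initial foreground probability near the (rare) tumor class prior,
        # preventing sigmoid saturation that stalls the Dice loss early on
        self.head.params["w"] *= 0.05
        self.head.params["b"][...] = -2.5
        self._skip_channels = ch

    # -- parameter bookkeeping ------------------------------------------------
    def _layers(self):
        for blocks in self.enc:
            yield from (b.conv for b in blocks)
            yield from (b.bn for b in blocks)
        yield from self.ups
        for blocks in self.dec:
            yield from (b.conv for b in blocks)
            yield from (b.bn for b in blocks)
        yield self.head

    def parameters(self):
        """Yield (layer, name, param, grad) tuples for the optimizer."""
        for layer in self._layers():
            for name, p in layer.params.items():
                yield layer, name, p, layer.grads[name]

    def zero_grad(self) -> None:
        for layer in self._layers():
            for g in layer.grads.values():
                g[...] = 0.0

    def param_checksum(self) -> float:
        return float(sum(np.abs(p).sum() for _, _, p, _ in self.parameters()))

    def n_parameters(self) -> int:
        return int(sum(p.size for _, _, p, _ in self.parameters()))

    # -- forward / backward ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, C, H, W) with H, W divisible by 2**(depth-1) -> (B, H, W) probs."""
        h, w = x.shape[2:]
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(f"input size {h}x{w} not divisible by 2^(depth-1)={div}")
        skips = []
        for lvl in range(self.depth):
            for blk in self.enc[lvl]:
                x = blk.forward(x, train)
            if lvl < self.depth - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x, train)
        self._concat_splits = []
        for i, lvl in enumerate(range(self.depth - 2, -1, -1)):
            x = self.ups[i].forward(x, train)
            skip = skips[lvl]
            x = np.concatenate([skip, x], axis=1)
            self._concat_splits.append(skip.shape[1])
            for blk in self.dec[i]:
                x = blk.forward(x, train)
        logits = self.head.forward(x, train)[:, 0]
        probs = 1.0 / (1.0 + np.exp(-logits))
        if train:
            self._probs = probs
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability map); accumulates gradients."""
        p = self._probs
        dlogits = (dprobs * p * (1.0 - p)).astype(p.dtype)[:, None]
        dx = self.head.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        for i in range(len(self.dec) - 1, -1, -1):
            lvl = self.depth - 2 - i
            for blk in reversed(self.dec[i]):
                dx = blk.backward(dx)
            nskip = self._concat_splits[i]
            dskips[lvl] = dx[:, :nskip]
            dx = self.ups[i].backward(np.ascontiguousarray(dx[:, nskip:]))
        for lvl in range(self.depth - 1, -1, -1):
            if lvl < self.depth - 1:
                dx = self.pools[lvl].backward(dx)
                dx = dx + dskips[lvl]
            for blk in reversed(self.enc[lvl]):
                dx = blk.backward(dx)

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            for name, p in layer.params.items():
                out[f"{i}.{name}"] = p
            if isinstance(layer, BatchNorm2D):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


class Adam:
    """Adam optimizer with bias correction, updating parameters in place."""

    def __init__(self, net: UNet2D, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for _, _, p, _ in net.parameters()]
        self._v = [np.zeros_like(p) for _, _, p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (_, _, p, g), m, v in zip(self.net.parameters(), self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def soft_dice_loss(
    pred: np.ndarray, target: np.ndarray, smooth: float = 1.0, with_grad: bool = False
):
    """Soft-Dice objective, averaged over the batch.

    For each sample ``1 - (2·Σ p·t + s) / (Σ p + Σ t + s)``; with binary
    predictions and s → 0 this is one minus the Dice similarity coefficient.

    Returns the scalar loss, or ``(loss, dloss/dpred)`` if `with_grad`.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if pred.ndim == 2:
        pred, target = pred[None], target[None]
        squeeze = True
    else:
        squeeze = False
    axes = tuple(range(1, pred.ndim))
    num = 2.0 * (pred * target).sum(axis=axes) + smooth
    den = pred.sum(axis=axes) + target.sum(axis=axes) + smooth
    loss = float(np.mean(1.0 - num / den))
    if not with_grad:
        return loss
    b = pred.shape[0]
    grad = -(2.0 * target * den[:, None, None] - num[:, None, None]) / den[:, None, None] ** 2 / b
    if squeeze:
        grad = grad[0]
    return loss, grad
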
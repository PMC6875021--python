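"""Minimal NumPy neural-network engine for 2-D segmentation.

Implements exactly the pieces the annulus segmentation network needs:
3x3 "same" convolutions via im2col + BLAS matmul, 1x1 convolutions, batch
normalisation, ReLU, 2x max pooling, nearest-neighbour upsampling, residual
blocks, and an encoder-decoder (U-shaped) network with skip connections.
Gradients are computed by hand-written backpropagation; the 3x3 convolution
backward pass reuses the forward convolution with flipped, transposed
kernels.  Everything runs in float32 on the CPU and is fully deterministic
given a seeded initialisation.

Tensors are channels-last ``(batch, height, width, channels)`` float32
arrays: with the channel axis contiguous, the im2col patch matrix is built
from nine plain block copies instead of a strided gather, which is what
keeps single-core training practical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "Conv1x1",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "Upsample2x",
    "ResidualBlock",
    "SegmentationUNet",
    "Adam",
    "sigmoid",
    "dice_bce_loss_grad",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _pad1(x: np.ndarray) -> np.ndarray:
    """Zero-pad the two spatial axes of a (B, H, W, C) tensor by one pixel."""
    b, h, w, c = x.shape
    xp = np.zeros((b, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    return xp


class Layer:
    """Base: forward caches what backward needs; params/grads are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero 'same' padding, with bias.

    Weights are stored as ``(3, 3, c_in, c_out)`` so the im2col product is a
    single GEMM against ``weights.reshape(9*c_in, c_out)``.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 9
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(3, 3, c_in, c_out))
        self.params = [w.astype(np.float32), np.zeros(c_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache: tuple | None = None

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
        # accumulate the nine kernel taps as (B*H*W, C) @ (C, O) GEMMs; each
        # shifted slice copy is contiguous, avoiding a strided im2col gather
        bs, h, ww, c_in = x.shape
        c_out = w.shape[3]
        xp = _pad1(x)
        out = np.zeros((bs * h * ww, c_out), dtype=np.result_type(x.dtype, w.dtype))
        for di in range(3):
            for dj in range(3):
                shifted = np.ascontiguousarray(xp[:, di : di + h, dj : dj + ww, :])
                out += shifted.reshape(-1, c_in) @ w[di, dj]
        if b is not None:
            out += b
        return out.reshape(bs, h, ww, c_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = (x,)
        return self._conv(x, self.params[0], self.params[1])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        w = self.params[0]
        bs, h, ww, c_in = x.shape
        xp = _pad1(x)
        dflat = dout.reshape(-1, w.shape[3])
        for di in range(3):
            for dj in range(3):
                shifted = np.ascontiguousarray(xp[:, di : di + h, dj : dj + ww, :])
                self.grads[0][di, dj] = shifted.reshape(-1, c_in).T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        # dx = conv(dout, kernel flipped spatially, in/out channels swapped)
        w_flip = np.ascontiguousarray(w[::-1, ::-1].transpose(0, 1, 3, 2))
        return self._conv(dout, w_flip, None)


class Conv1x1(Layer):
    """1x1 convolution (channel mixing), used for the output head."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.params = [w.astype(np.float32), np.zeros(c_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = (x,)
        return x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (x,) = self._cache
        c_in, c_out = self.params[0].shape
        self.grads[0][...] = x.reshape(-1, c_in).T @ dout.reshape(-1, c_out)
        self.grads[1][...] = dout.reshape(-1, c_out).sum(axis=0)
        return dout @ self.params[0].T


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params = [np.ones(c, dtype=np.float32), np.zeros(c, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return gamma * xhat + beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        gamma = self.params[0]
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * gamma
        term = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2), keepdims=True) / m
        )
        return term * inv_std


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        xr = np.ascontiguousarray(
            x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(b, h // 2, w // 2, 4, c)
        idx = xr.argmax(axis=3)
        if train:
            self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (b, h, w, c) = self._cache
        flat = np.zeros((b, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(flat, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return (
            flat.reshape(b, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, c)
        )


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = dout.shape
        return dout.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class _Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN plus identity shortcut, then ReLU."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.body = _Sequential(
            [Conv3x3(c, c, rng), BatchNorm2d(c), ReLU(), Conv3x3(c, c, rng), BatchNorm2d(c)]
        )
        self.out_relu = ReLU()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.out_relu.forward(self.body.forward(x, train) + x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.out_relu.backward(dout)
        return self.body.backward(d) + d


def _collect(layer: Layer) -> list[Layer]:
    """Depth-first list of primitive layers, deterministic order."""
    if isinstance(layer, _Sequential):
        out: list[Layer] = []
        for sub in layer.layers:
            out.extend(_collect(sub))
        return out
    if isinstance(layer, ResidualBlock):
        return _collect(layer.body) + [layer.out_relu]
    return [layer]


class SegmentationUNet:
    """Encoder-decoder residual segmentation network with skip connections.

    ``depth`` levels of (channel-expanding conv, residual blocks, 2x
    downsampling), a residual bottleneck, and a mirrored decoder that
    upsamples, halves channels, concatenates the same-scale encoder output
    and applies residual blocks.  A 1x1 convolution produces single-channel
    logits; callers apply the sigmoid.
    """

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 4,
        blocks_per_level: int = 1,
        in_channels: int = 1,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_channels = base_channels
        self.blocks_per_level = blocks_per_level

        def level(c_in: int, c_out: int) -> _Sequential:
            layers: list[Layer] = [Conv3x3(c_in, c_out, rng), BatchNorm2d(c_out), ReLU()]
            layers += [ResidualBlock(c_out, rng) for _ in range(blocks_per_level)]
            return _Sequential(layers)

        chans = [base_channels * 2**d for d in range(depth + 1)]
        self.enc = []
        c_prev = in_channels
        for d in range(depth):
            self.enc.append(level(c_prev, chans[d]))
            c_prev = chans[d]
        self.pools = [MaxPool2x2() for _ in range(depth)]
        self.bottleneck = level(c_prev, chans[depth])
        self.ups = [Upsample2x() for _ in range(depth)]
        self.up_convs = []
        self.dec = []
        c_prev = chans[depth]
        for d in reversed(range(depth)):
            self.up_convs.append(Conv3x3(c_prev, chans[d], rng))
            self.dec.append(level(chans[d] * 2, chans[d]))
            c_prev = chans[d]
        self.head = Conv1x1(chans[0], 1, rng)

        modules: list[Layer] = []
        for m in self.enc + self.pools + [self.bottleneck] + self.ups + self.up_convs + self.dec:
            modules.extend(_collect(m))
        modules.append(self.head)
        self._layers = modules

    # -- parameter access -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers for g in layer.grads]

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        arrays = list(self.parameters)
        for layer in self._layers:
            if isinstance(layer, BatchNorm2d):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def set_state(self, arrays: list[np.ndarray]) -> None:
        current = self.state_arrays()
        if len(arrays) != len(current):
            raise ValueError(f"state length mismatch: {len(arrays)} != {len(current)}")
        for dst, src in zip(current, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} != {src.shape}")
            dst[...] = src

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, H, W, 1) input -> (B, H, W, 1) logits."""
        skips = []
        h = x.astype(np.float32, copy=False)
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for i, (up, conv, dec) in enumerate(zip(self.ups, self.up_convs, self.dec)):
            h = conv.forward(up.forward(h, train), train)
            skip = skips[self.depth - 1 - i]
            h = dec.forward(np.concatenate([skip, h], axis=-1), train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = [None] * self.depth
        for i in reversed(range(self.depth)):
            dcat = self.dec[i].backward(d)
            c_skip = dcat.shape[-1] // 2
            dskips[self.depth - 1 - i] = dcat[..., :c_skip]
            d = self.ups[i].backward(self.up_convs[i].backward(dcat[..., c_skip:]))
        d = self.bottleneck.backward(d)
        for i in reversed(range(self.depth)):
            d = self.pools[i].backward(d)
            d = self.enc[i].backward(d + dskips[i])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))


class Adam:
    """Adam optimiser over a flat parameter/gradient list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def dice_bce_loss_grad(
    logits: np.ndarray, targets: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Equal-weight soft-Dice + binary-cross-entropy loss and its logit gradient.

    The soft Dice term is computed over the whole batch; ``eps`` smooths the
    all-empty case.  Returns (scalar loss, dL/dlogits).
    """
    p = sigmoid(logits)
    t = targets.astype(np.float32, copy=False)
    n = logits.size

    # BCE in a numerically safe form: log(1+e^-|z|) + max(z,0) - z*t
    z = logits
    bce = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * t))
    dbce = (p - t) / n

    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    # d(1 - dice)/dp, then chain through the sigmoid
    ddice_dp = (2.0 * t * denom - (2.0 * inter + eps)) / denom**2
    ddice = -ddice_dp * p * (1.0 - p)

    return bce + (1.0 - dice), (dbce + ddice).astype(np.float32)
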
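"""Minimal NumPy layer stack for small 3D convolutional networks.

Implements exactly the operations the segmentation backbone needs —
3D convolution (valid or zero-padded), ReLU, sigmoid, 2x2x2 max-pooling,
2x2x2 strided up-convolution — each with a hand-derived backward pass,
plus the Adam optimizer. Data layout is channels-first: ``(C, D, H, W)``
for a single volume (the training batch size is one volume).

Convolutions are direct (no im2col expansion): when numba is available
they run as JIT-compiled tap loops, otherwise as one small GEMM per
kernel tap over contiguous shifted slices of the input. Both paths
share the same tap decomposition in the backward pass (scatter-add for
the input gradient, tap-wise accumulation for the weight gradient) and
were verified against finite differences.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

try:  # pragma: no cover - exercised implicitly by every conv test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "UpConv3d",
    "Adam",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward caches what backward needs (training mode only)."""

    def parameters(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _offsets(k: int):
    return [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)]


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _nb_conv_fwd(x, w):  # pragma: no cover - compiled
        cin, d, h, wd = x.shape
        cout, _, k, _, _ = w.shape
        oz, oy, ox = d - k + 1, h - k + 1, wd - k + 1
        out = np.zeros((cout, oz, oy, ox), dtype=np.float32)
        for z in range(oz):
            for y in range(oy):
                for co in range(cout):
                    orow = out[co, z, y]
                    for ci in range(cin):
                        for dz in range(k):
                            for dy in range(k):
                                xrow = x[ci, z + dz, y + dy]
                                for dx in range(k):
                                    wv = w[co, ci, dz, dy, dx]
                                    for xx in range(ox):
                                        orow[xx] += wv * xrow[xx + dx]
        return out

    @njit(cache=True, fastmath=True)
    def _nb_conv_bwd(xp, w, g):  # pragma: no cover - compiled
        cin = xp.shape[0]
        cout, _, k, _, _ = w.shape
        oz, oy, ox = g.shape[1], g.shape[2], g.shape[3]
        gw = np.zeros(w.shape, dtype=np.float32)
        gx = np.zeros(xp.shape, dtype=np.float32)
        for co in range(cout):
            for ci in range(cin):
                for dz in range(k):
                    for dy in range(k):
                        for dx in range(k):
                            wv = w[co, ci, dz, dy, dx]
                            acc = np.float32(0.0)
                            for z in range(oz):
                                for y in range(oy):
                                    grow = g[co, z, y]
                                    xrow = xp[ci, z + dz, y + dy]
                                    gxrow = gx[ci, z + dz, y + dy]
                                    for xx in range(ox):
                                        gv = grow[xx]
                                        acc += xrow[xx + dx] * gv
                                        gxrow[xx + dx] += wv * gv
                            gw[co, ci, dz, dy, dx] = acc
        return gw, gx


def _corr3d(x: np.ndarray, weight: np.ndarray, pad: int) -> Tuple[np.ndarray, np.ndarray]:
    """Cross-correlate ``x`` (C_in,D,H,W) with ``weight`` (C_out,C_in,k,k,k).

    Evaluated as one small GEMM per kernel tap over a contiguous shifted
    slice of the input — much cheaper in memory traffic than a full
    im2col expansion for the narrow channel counts used here. Returns
    the output (C_out, D', H', W') and the (possibly padded) input it
    was computed from, for reuse by the backward pass.
    """
    k = weight.shape[-1]
    if pad > 0:
        x = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    x = np.ascontiguousarray(x, dtype=np.float32)
    if _HAVE_NUMBA:
        return _nb_conv_fwd(x, np.ascontiguousarray(weight)), x
    cin = x.shape[0]
    cout = weight.shape[0]
    out_spatial = tuple(s - (k - 1) for s in x.shape[1:])
    n = int(np.prod(out_spatial))
    out = np.zeros((cout, n), dtype=np.float32)
    for dz, dy, dx in _offsets(k):
        xs = np.ascontiguousarray(
            x[
                :,
                dz : dz + out_spatial[0],
                dy : dy + out_spatial[1],
                dx : dx + out_spatial[2],
            ]
        ).reshape(cin, n)
        out += weight[:, :, dz, dy, dx] @ xs
    return out.reshape((cout,) + out_spatial), x


class Conv3d(Layer):
    """k^3 convolution, either 'valid' (no padding) or 'same' (zero-padded).

    Valid mode shrinks each spatial axis by k-1; same mode preserves it.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        padding: str = "valid",
        rng: Optional[np.random.Generator] = None,
        name: str = "conv",
    ) -> None:
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        if padding == "same" and kernel_size % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.pad = 0 if padding == "valid" else (kernel_size - 1) // 2
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size ** 3
        std = float(np.sqrt(2.0 / fan_in))  # Kaiming fan-in, ReLU gain
        w = rng.normal(0.0, std, size=(out_channels, in_channels) + (kernel_size,) * 3)
        self.weight = Parameter(w, name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), name=f"{name}.bias")
        self._cache: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def output_shape(self, spatial: Sequence[int]) -> Tuple[int, ...]:
        if self.padding == "same":
            return tuple(spatial)
        return tuple(s - (self.kernel_size - 1) for s in spatial)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out, x_padded = _corr3d(x, self.weight.value, self.pad)
        out += self.bias.value[:, None, None, None]
        self._cache = x_padded if train else None
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a training-mode forward")
        x_padded = self._cache
        k = self.kernel_size
        cin = x_padded.shape[0]
        oz, oy, ox = grad_out.shape[1:]
        n = oz * oy * ox
        grad_out = np.ascontiguousarray(grad_out, dtype=np.float32)
        g2 = grad_out.reshape(self.out_channels, n)
        self.bias.grad += g2.sum(axis=1)
        # weight grad: one tap at a time against the shifted input slices;
        # input grad: scatter-add of W^T @ grad_out into the padded shape
        w = self.weight.value
        if _HAVE_NUMBA:
            gw, grad_padded = _nb_conv_bwd(x_padded, np.ascontiguousarray(w), grad_out)
            self.weight.grad += gw
        else:
            grad_padded = np.zeros_like(x_padded)
            for dz, dy, dx in _offsets(k):
                sl = (slice(None), slice(dz, dz + oz), slice(dy, dy + oy),
                      slice(dx, dx + ox))
                xs = np.ascontiguousarray(x_padded[sl]).reshape(cin, n)
                self.weight.grad[:, :, dz, dy, dx] += g2 @ xs.T
                grad_padded[sl] += (
                    w[:, :, dz, dy, dx].T @ g2
                ).reshape(cin, oz, oy, ox)
        if self.pad > 0:
            grad_in = np.ascontiguousarray(
                grad_padded[:, self.pad:-self.pad, self.pad:-self.pad,
                            self.pad:-self.pad]
            )
        else:
            grad_in = grad_padded
        self._cache = None
        return grad_in


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        with np.errstate(over="ignore"):  # exp overflow saturates to 0/1
            out = 1.0 / (1.0 + np.exp(-x))
        self._out = out if train else None
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._out * (1.0 - self._out)


class MaxPool3d(Layer):
    """Non-overlapping pooling with factor ``f`` (spatial sizes must divide)."""

    def __init__(self, factor: int = 2) -> None:
        self.factor = factor
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        c, d, h, w = x.shape
        if d % f or h % f or w % f:
            raise ValueError(f"spatial shape {x.shape[1:]} not divisible by {f}")
        blocks = x.reshape(c, d // f, f, h // f, f, w // f, f)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
            c, d // f, h // f, w // f, f ** 3
        )
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape) if train else None
        return np.ascontiguousarray(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        idx, in_shape = self._cache
        f = self.factor
        c, d, h, w = in_shape
        blocks = np.zeros((c, d // f, h // f, w // f, f ** 3), dtype=grad_out.dtype)
        np.put_along_axis(blocks, idx[..., None], grad_out[..., None], axis=-1)
        blocks = blocks.reshape(c, d // f, h // f, w // f, f, f, f)
        blocks = blocks.transpose(0, 1, 4, 2, 5, 3, 6)
        self._cache = None
        return np.ascontiguousarray(blocks.reshape(in_shape))


class UpConv3d(Layer):
    """Learned upsampling: transposed convolution with kernel == stride == f.

    Every output voxel receives exactly one kernel contribution, so both
    directions are plain tensor contractions.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        factor: int = 2,
        rng: Optional[np.random.Generator] = None,
        name: str = "upconv",
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.factor = factor
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels  # each output voxel sees one input voxel per channel
        std = float(np.sqrt(2.0 / fan_in))
        w = rng.normal(0.0, std, size=(in_channels, out_channels) + (factor,) * 3)
        self.weight = Parameter(w, name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), name=f"{name}.bias")
        self._x: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        c, d, h, w = x.shape
        # (Cout, f, f, f, D, H, W)
        blocks = np.tensordot(self.weight.value, x, axes=([0], [0]))
        out = blocks.transpose(0, 4, 1, 5, 2, 6, 3).reshape(
            self.out_channels, d * f, h * f, w * f
        )
        out = np.ascontiguousarray(out)
        out += self.bias.value[:, None, None, None]
        self._x = x if train else None
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        f = self.factor
        co, df, hf, wf = grad_out.shape
        d, h, w = df // f, hf // f, wf // f
        g = grad_out.reshape(co, d, f, h, f, w, f).transpose(0, 2, 4, 6, 1, 3, 5)
        # g: (Cout, f, f, f, D, H, W)
        self.weight.grad += np.tensordot(self._x, g, axes=([1, 2, 3], [4, 5, 6]))
        self.bias.grad += grad_out.sum(axis=(1, 2, 3))
        grad_in = np.tensordot(
            self.weight.value, g, axes=([1, 2, 3, 4], [0, 1, 2, 3])
        )
        self._x = None
        return np.ascontiguousarray(grad_in)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Parameters."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-4,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
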
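"""Minimal trainable 1-D convolution engine (forward + analytic backward).

Implements exactly the layer set the surrogate architectures need — strided
1-D convolutions, stride-2 transposed convolutions, tanh/sigmoid/PReLU
activations, channel concatenation and an Adam optimiser — on plain numpy
arrays of shape ``(batch, channels, time)``.

Conventions
-----------
* Stride-2 convolutions halve the temporal dimension exactly: for kernel
  ``k`` and stride ``s`` the input is zero-padded by ``k - s`` samples total,
  split ``(k - s) // 2`` left and the remainder right, so ``T -> T // s``.
* A transposed convolution is defined as the exact linear adjoint of that
  convolution, so it doubles the temporal dimension exactly and the
  conv/conv-transpose pair satisfies ``<conv(x), y> == <x, convT(y)>`` for
  shared weights (a property the test-suite checks).  This also means the
  backward pass of each is the forward pass of the other.
* All parameters are float64; gradients are accumulated in ``.g*`` buffers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d", "ConvTranspose1d", "Tanh", "Sigmoid", "PReLU", "Identity",
    "Adam", "ACTIVATIONS",
]


def _pad_lr(k: int, stride: int) -> tuple[int, int]:
    total = k - stride
    if total < 0:
        raise ValueError("kernel must be >= stride")
    return total // 2, total - total // 2


def _conv_patches(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Zero-pad and extract strided patches: (B, C, T) -> (B, C, T_out, k)."""
    pl, pr = _pad_lr(k, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    return sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]


def _conv_forward(x: np.ndarray, W: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """y[b,o,t] = sum_{c,j} x_patches[b,c,t,j] * W[o,c,j]; returns (y, patches)."""
    k = W.shape[-1]
    patches = _conv_patches(x, k, stride)
    B, C, To, _ = patches.shape
    P = np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(B * To, C * k)
    y = P @ W.reshape(W.shape[0], C * k).T
    return y.reshape(B, To, W.shape[0]).transpose(0, 2, 1), patches


def _conv_weight_grad(patches: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """gW[o,c,j] = sum_{b,t} patches[b,c,t,j] * gy[b,o,t]."""
    B, C, To, k = patches.shape
    P = np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(B * To, C * k)
    G = np.ascontiguousarray(gy.transpose(0, 2, 1)).reshape(B * To, gy.shape[1])
    return (G.T @ P).reshape(gy.shape[1], C, k)


def _conv_input_grad(gy: np.ndarray, W: np.ndarray, stride: int, T_in: int) -> np.ndarray:
    """Adjoint of the strided conv: scatter gy back onto the (padded) input grid."""
    Co, Ci, k = W.shape
    pl, pr = _pad_lr(k, stride)
    B, _, To = gy.shape
    Tp = T_in + pl + pr
    # contrib[b,c,t,j] = sum_o gy[b,o,t] W[o,c,j]
    G = np.ascontiguousarray(gy.transpose(0, 2, 1)).reshape(B * To, Co)
    contrib = (G @ W.reshape(Co, Ci * k)).reshape(B, To, Ci, k).transpose(0, 2, 1, 3)
    gxp = np.zeros((B, Ci, Tp))
    for j in range(k):
        gxp[:, :, j : j + stride * To : stride] += contrib[:, :, :, j]
    return gxp[:, :, pl : pl + T_in]


class Conv1d:
    """Strided 1-D convolution with bias; ``T -> T // stride``."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_ch * kernel)
        self.W = rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel))
        self.b = rng.uniform(-bound, bound, size=out_ch)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % self.stride:
            raise ValueError(f"input length {x.shape[2]} not divisible by stride {self.stride}")
        y, patches = _conv_forward(x, self.W, self.stride)
        self._cache = (patches, x.shape[2])
        return y + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        patches, T_in = self._cache
        self.gW += _conv_weight_grad(patches, gy)
        self.gb += gy.sum(axis=(0, 2))
        return _conv_input_grad(gy, self.W, self.stride, T_in)

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ConvTranspose1d:
    """Transposed stride-2 convolution: exact adjoint of :class:`Conv1d`.

    Weight shape is ``(out_ch, in_ch, kernel)`` when viewed as the underlying
    convolution's weight, i.e. the layer maps ``in_ch -> out_ch`` channels and
    ``T -> T * stride`` samples; bias is added on the output channels.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_ch * kernel)
        # W indexed [in_ch, out_ch, k]: the adjoint of a conv mapping out->in.
        self.W = rng.uniform(-bound, bound, size=(in_ch, out_ch, kernel))
        self.b = rng.uniform(-bound, bound, size=out_ch)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        T_out = x.shape[2] * self.stride
        y = _conv_input_grad(x, self.W, self.stride, T_out)
        self._cache = (x, T_out)
        return y + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, _ = self._cache
        gy_patches = _conv_patches(gy, self.kernel, self.stride)
        self.gW += _conv_weight_grad(gy_patches, x)
        self.gb += gy.sum(axis=(0, 2))
        gx, _ = _conv_forward(gy, self.W, self.stride)
        return gx

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class Tanh:
    n_params = 0

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y ** 2)

    def params(self):
        return []


class Sigmoid:
    n_params = 0

    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)

    def params(self):
        return []


class Identity:
    n_params = 0

    def forward(self, x):
        return x

    def backward(self, gy):
        return gy

    def params(self):
        return []


class PReLU:
    """Parametric ReLU with one learnable slope per channel (shared over time)."""

    def __init__(self, n_ch: int, init: float = 0.25):
        self.a = np.full(n_ch, init)
        self.ga = np.zeros_like(self.a)

    def forward(self, x):
        self._x = x
        self._neg = x < 0
        return np.where(self._neg, self.a[None, :, None] * x, x)

    def backward(self, gy):
        self.ga += np.sum(gy * self._x * self._neg, axis=(0, 2))
        return np.where(self._neg, self.a[None, :, None] * gy, gy)

    def params(self):
        return [("a", self.a, self.ga)]

    @property
    def n_params(self) -> int:
        return self.a.size


def make_activation(tag: str, n_ch: int):
    if tag == "tanh":
        return Tanh()
    if tag == "sigmoid":
        return Sigmoid()
    if tag == "prelu":
        return PReLU(n_ch)
    if tag in ("linear", "none"):
        return Identity()
    raise ValueError(f"unknown activation {tag!r}")


ACTIVATIONS = ("tanh", "sigmoid", "prelu", "linear")


class Adam:
    """Adam optimiser over a flat list of (array, grad) pairs."""

    def __init__(self, param_pairs, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_pairs)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0.0
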
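"""Minimal convolutional-network machinery (NumPy, CPU).

Layers implement ``forward`` / ``backward`` with explicit parameter and
gradient arrays; convolutions use im2col so the heavy lifting is a single
matrix product per layer.  Arrays are float32, NCHW.  This is deliberately a
small, auditable engine: the networks built on it are a few strided
convolutions followed by global average pooling and a one-unit dense head.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list  # list of [name, value, grad]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with stride and symmetric zero pad."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.w, self.b = w, b
        self.gw = np.zeros_like(w)
        self.gb = np.zeros_like(b)
        self.params = [["w", self.w, self.gw], ["b", self.b, self.gb]]
        self._cache = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        n, c, h, w = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # N,C,Ho,Wo,k,k
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * self.k * self.k, ho * wo)
        return np.ascontiguousarray(cols), (ho, wo)

    def forward(self, x, train=False):
        cols, (ho, wo) = self._im2col(x)
        y = np.einsum("of,nfl->nol", self.w, cols, optimize=True) + self.b[None, :, None]
        if train:
            self._cache = (cols, x.shape, (ho, wo))
        return y.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dy):
        cols, x_shape, (ho, wo) = self._cache
        n, c, h, w = x_shape
        dy_mat = dy.reshape(n, self.c_out, ho * wo)
        self.gw[...] = np.einsum("nol,nfl->of", dy_mat, cols, optimize=True)
        self.gb[...] = dy_mat.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.w, dy_mat, optimize=True)
        dcols = dcols.reshape(n, c, self.k, self.k, ho, wo)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dxp = np.zeros((n, c, hp, wp), dtype=dy.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class GlobalAvgPool(Layer):
    """N,C,H,W → N,C spatial mean."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    """Fully connected N,C → N,units."""

    def __init__(self, c_in: int, units: int, rng):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(units, c_in)).astype(np.float32)
        b = np.zeros(units, dtype=np.float32)
        self.w, self.b = w, b
        self.gw = np.zeros_like(w)
        self.gb = np.zeros_like(b)
        self.params = [["w", self.w, self.gw], ["b", self.b, self.gb]]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.gw[...] = dy.T @ self._x
        self.gb[...] = dy.sum(axis=0)
        return dy @ self.w


class RMSprop:
    """RMSprop with the usual rho=0.9 accumulator."""

    def __init__(self, layers: list[Layer], lr: float, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.slots = []
        for layer in layers:
            for name, value, grad in layer.params:
                self.slots.append((value, grad, np.zeros_like(value)))

    def step(self):
        for value, grad, cache in self.slots:
            cache *= self.rho
            cache += (1.0 - self.rho) * grad * grad
            value -= self.lr * grad / (np.sqrt(cache) + self.eps)


class ConvNet:
    """Conv/ReLU trunk + global average pooling + single-unit dense head.

    ``trunk`` ends with the final convolutional feature map (post-ReLU),
    which is exposed for Grad-CAM via :meth:`features`.
    """

    def __init__(self, trunk: list[Layer], head_dense: Dense):
        self.trunk = trunk
        self.gap = GlobalAvgPool()
        self.head = head_dense
        self.layers = trunk + [self.gap, self.head]

    # -- inference -----------------------------------------------------
    def features(self, x: np.ndarray) -> np.ndarray:
        """Final convolutional feature map, N,C,H,W."""
        for layer in self.trunk:
            x = layer.forward(x, train=False)
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x[:, 0]

    def backward_from_output(self, dout: np.ndarray) -> None:
        dy = dout[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    # -- introspection -------------------------------------------------
    @property
    def head_weights(self) -> tuple[np.ndarray, float]:
        return self.head.w[0].copy(), float(self.head.b[0])

    def parameter_count(self) -> int:
        return sum(value.size for layer in self.layers for _, value, _ in layer.params)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, value, _ in layer.params:
                out[f"layer{i}_{name}"] = value
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for slot in layer.params:
                key = f"layer{i}_{slot[0]}"
                if key not in arrays:
                    raise KeyError(f"checkpoint missing parameter {key}")
                if slot[1].shape != arrays[key].shape:
                    raise ValueError(f"shape mismatch for {key}")
                slot[1][...] = arrays[key]
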
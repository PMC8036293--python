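"""Minimal 3D convolutional network engine in NumPy.

Explicit forward/backward layers sized for desk-scale volumetric
classification on one CPU.  Convolutions are computed as 27 GEMMs (one per
kernel offset) so the heavy lifting stays inside BLAS; activations use the
internal layout ``(channels, batch, depth, height, width)`` so each offset
slice reshapes to a ``(C_in, batch * voxels)`` matrix.

Design points:

* valid 3x3x3 convolutions (stride 1, no padding) and 2x2x2 max pooling
  (stride 2, floor semantics);
* ReLU non-linearities; fully connected head; softmax cross-entropy loss;
* plain stochastic gradient descent;
* everything float32, deterministic for a fixed seed (first-occurrence
  tie-break in pooling argmax).
"""

from __future__ import annotations

import ctypes

import numpy as np

# Large activation buffers are allocated and freed every forward pass; with
# glibc's default mmap threshold each one round-trips through mmap/munmap and
# the kernel's page zeroing, which dominates runtime.  Raising the threshold
# lets the heap recycle those buffers.  Best effort: silently skipped on
# non-glibc platforms.
try:  # pragma: no cover - platform dependent
    _libc = ctypes.CDLL("libc.so.6")
    _libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD = -3
except (OSError, AttributeError):
    pass

__all__ = ["Conv3d", "MaxPool3d", "ReLU", "Flatten", "Linear",
           "softmax", "cross_entropy_with_grad", "Sequential"]


def _as_f32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


class Layer:
    """Base layer: ``forward`` stores what ``backward`` needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """Valid 3x3x3 convolution, stride 1, computed as one im2col GEMM.

    The column matrix has shape ``(C_in * 27, batch * out_voxels)``; forward
    is a single BLAS call ``W2d @ col``, backward two more
    (``g @ col.T`` for the weights, ``W2d.T @ g`` scattered back for the
    input gradient).  The column buffer for the widest layer of the default
    network is a few hundred MB per pair of samples, which is why training
    processes small accumulation chunks.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 need_input_grad: bool = True) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.need_input_grad = need_input_grad
        fan_in = c_in * 27
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.params["W"] = rng.normal(0.0, std, size=(c_out, c_in, 3, 3, 3)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    @staticmethod
    def _im2col(x: np.ndarray, do: int, ho: int, wo: int) -> np.ndarray:
        c, b = x.shape[:2]
        n = b * do * ho * wo
        col = np.empty((c, 27, n), dtype=np.float32)
        off = 0
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    col[:, off, :] = x[:, :, i : i + do, j : j + ho, k : k + wo].reshape(c, n)
                    off += 1
        return col.reshape(c * 27, n)

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (C_in, B, D, H, W); the column matrix is kept for backward
        c, b, d, h, w = x.shape
        do, ho, wo = d - 2, h - 2, w - 2
        if min(do, ho, wo) < 1:
            raise ValueError("spatial extent too small for a 3x3x3 convolution")
        self._col = self._im2col(x, do, ho, wo)
        self._in_shape = x.shape
        w2d = self.params["W"].reshape(self.c_out, c * 27)
        out = w2d @ self._col
        out += self.params["b"][:, None]
        return out.reshape(self.c_out, b, do, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, b, d, h, w = self._in_shape
        _, _, do, ho, wo = dout.shape
        n = b * do * ho * wo
        g = _as_f32(dout).reshape(self.c_out, n)
        self.grads["W"] = (g @ self._col.T).reshape(self.params["W"].shape)
        self.grads["b"] = g.sum(axis=1)
        self._col = None
        dx = None
        if self.need_input_grad:
            # contiguous transpose: BLAS runs several times faster on it here
            w2d_t = np.ascontiguousarray(self.params["W"].reshape(self.c_out, c * 27).T)
            dcol = (w2d_t @ g).reshape(c, 27, b, do, ho, wo)
            dx = np.zeros(self._in_shape, dtype=np.float32)
            off = 0
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        dx[:, :, i : i + do, j : j + ho, k : k + wo] += dcol[:, off]
                        off += 1
        return dx


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2 (floor semantics).

    Forward reduces by pairwise maxima (one cheap pass per axis).  Backward
    routes the gradient to every cell equal to its block maximum — a
    deterministic subgradient.  Exact ties between positive activations have
    measure zero; the common all-zero post-ReLU blocks do tie, but their
    duplicated gradient is annihilated by the preceding ReLU mask.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, b, d, h, w = x.shape
        dp, hp, wp = d // 2, h // 2, w // 2
        if min(dp, hp, wp) < 1:
            raise ValueError("spatial extent too small for 2x2x2 pooling")
        xv = x[:, :, : 2 * dp, : 2 * hp, : 2 * wp]
        m = np.maximum(xv[..., ::2], xv[..., 1::2])
        m = np.maximum(m[..., ::2, :], m[..., 1::2, :])
        m = np.maximum(m[:, :, ::2, :, :], m[:, :, 1::2, :, :])
        self._x = x
        self._max = m
        return m

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        c, b, d, h, w = x.shape
        dp, hp, wp = d // 2, h // 2, w // 2
        xv = x[:, :, : 2 * dp, : 2 * hp, : 2 * wp]
        mfull = self._max.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
        dfull = _as_f32(dout).repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
        grad = np.where(xv == mfull, dfull, np.float32(0.0))
        if xv.shape == x.shape:
            dx = grad
        else:
            dx = np.zeros(x.shape, dtype=np.float32)
            dx[:, :, : 2 * dp, : 2 * hp, : 2 * wp] = grad
        self._x = None
        self._max = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        np.maximum(x, np.float32(0.0), out=x)  # in place: x is layer-owned
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout *= self._mask
        self._mask = None
        return dout


class Flatten(Layer):
    """(C, B, D, H, W) -> (C*D*H*W, B), per-sample feature vectors."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        c, b = x.shape[:2]
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3, 4)).reshape(b, -1).T

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, b, d, h, w = self._shape
        return np.ascontiguousarray(dout.T).reshape(b, c, d, h, w).transpose(1, 0, 2, 3, 4)


class Linear(Layer):
    """Fully connected layer on (features, batch) activations."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu_gain: bool = True) -> None:
        super().__init__()
        std = np.sqrt((2.0 if relu_gain else 1.0) / n_in)
        self.params["W"] = rng.normal(0.0, std, size=(n_out, n_in)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self.params["W"] @ x + self.params["b"][:, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout @ self._x.T
        self.grads["b"] = dout.sum(axis=1)
        dx = self.params["W"].T @ dout
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    """Column-wise softmax of (classes, batch) logits."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def cross_entropy_with_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy, its gradient w.r.t. logits, and the probabilities.

    ``logits``: (classes, batch); ``labels``: int class indices (batch,).
    The gradient is already divided by the batch size.
    """
    p = softmax(logits.astype(np.float64))
    b = logits.shape[1]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[labels, np.arange(b)] + eps)))
    grad = p.copy()
    grad[labels, np.arange(b)] -= 1.0
    return loss, (grad / b).astype(np.float32), p.astype(np.float32)


class Sequential:
    """A plain layer stack with SGD updates."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def zero_grad_accumulators(self) -> dict[int, dict[str, np.ndarray]]:
        return {
            i: {k: np.zeros_like(v) for k, v in layer.params.items()}
            for i, layer in enumerate(self.layers)
            if layer.params
        }

    def accumulate_grads(self, acc: dict[int, dict[str, np.ndarray]], weight: float) -> None:
        for i, bucket in acc.items():
            for k in bucket:
                bucket[k] += weight * self.layers[i].grads[k]

    def sgd_step(self, acc: dict[int, dict[str, np.ndarray]], lr: float) -> None:
        for i, bucket in acc.items():
            for k, g in bucket.items():
                self.layers[i].params[k] -= lr * g

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"layer{i}.{k}"] = v
        return out

    def load_parameters(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            name, pname = key.split(".")
            i = int(name.removeprefix("layer"))
            if self.layers[i].params[pname].shape != value.shape:
                raise ValueError(f"shape mismatch for {key}")
            self.layers[i].params[pname] = value.astype(np.float32)

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())
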
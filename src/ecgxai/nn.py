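"""Minimal 1D neural-network engine on numpy arrays.

Layers operate on batches shaped ``(N, C, L)`` and implement explicit
``forward``/``backward`` passes; convolution is im2col + BLAS matmul, so a
desk-scale residual network trains on a single CPU in minutes.  The same
backward pass that trains the network also delivers the feature-map
gradients Grad-CAM needs, captured at arbitrary block outputs.

Everything is deterministic given the initialization seed: no threading-
dependent reductions, no unseeded draws.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool",
    "Linear",
    "ResidualBlock",
    "Adam",
    "softmax",
    "cross_entropy_grad",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> List[Dict]:
        return []


class Conv1d(Layer):
    """Same-padded 1D convolution (zero padding), optional stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.kernel = kernel
        self.pad = (kernel - 1) // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        # (N, C, L_out, K) -> (N, L_out, C*K)
        col = win.transpose(0, 2, 1, 3).reshape(n, win.shape[2], c * k)
        self._col = col
        self._in_shape = x.shape
        wf = self.w.reshape(self.w.shape[0], c * k).T
        out = col @ wf + self.b
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        k, s, p = self.kernel, self.stride, self.pad
        gt = grad.transpose(0, 2, 1)  # (N, L_out, c_out)
        l_out = gt.shape[1]
        c_out = self.w.shape[0]
        self.dw += (
            gt.reshape(-1, c_out).T @ self._col.reshape(-1, c * k)
        ).reshape(c_out, c, k)
        self.db += grad.sum(axis=(0, 2))
        wf = self.w.reshape(c_out, c * k)
        dcol = (gt @ wf).reshape(n, l_out, c, k).transpose(0, 2, 1, 3)  # (N,C,L_out,K)
        dxp = np.zeros((n, c, length + 2 * p), dtype=np.float32)
        for j in range(k):
            dxp[:, :, j : j + s * l_out : s] += dcol[:, :, :, j]
        self._col = None
        return dxp[:, :, p : p + length]

    def parameters(self) -> List[Dict]:
        return [
            {"value": self.w, "grad": self.dw},
            {"value": self.b, "grad": self.db},
        ]


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and time, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._training = training
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._invstd[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.dgamma += (grad * xhat).sum(axis=(0, 2))
        self.dbeta += grad.sum(axis=(0, 2))
        g = grad * self.gamma[None, :, None]
        if not self._training:
            return g * invstd[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        dx = (
            g - g.mean(axis=(0, 2), keepdims=True)
            - xhat * (g * xhat).sum(axis=(0, 2), keepdims=True) / m
        ) * invstd[None, :, None]
        self._xhat = None
        return dx

    def parameters(self) -> List[Dict]:
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        l_out = length // self.size
        self._in_len = length
        xv = x[:, :, : l_out * self.size].reshape(n, c, l_out, self.size)
        self._argmax = xv.argmax(axis=3)
        return xv.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, l_out = grad.shape
        dx = np.zeros((n, c, self._in_len), dtype=grad.dtype)
        dxv = dx[:, :, : l_out * self.size].reshape(n, c, l_out, self.size)
        ni, ci, li = np.ogrid[:n, :c, :l_out]
        dxv[ni, ci, li, self._argmax] = grad
        return dx


class GlobalAvgPool(Layer):
    """(N, C, L) -> (N, C) mean over time; makes the net length-agnostic."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw += self._x.T @ grad
        self.db += grad.sum(axis=0)
        self._x = None
        return grad @ self.w.T

    def parameters(self) -> List[Dict]:
        return [
            {"value": self.w, "grad": self.dw},
            {"value": self.b, "grad": self.db},
        ]


class ResidualBlock(Layer):
    """conv–BN–ReLU–conv–BN plus shortcut, ReLU after the addition.

    A 1x1 projection (with BN) carries the shortcut whenever the block
    changes channel count or stride; otherwise the shortcut is identity.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride=stride, rng=rng)
        self.bn1 = BatchNorm1d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, kernel, stride=1, rng=rng)
        self.bn2 = BatchNorm1d(c_out)
        self.projection: Optional[Conv1d] = None
        self.proj_bn: Optional[BatchNorm1d] = None
        if c_in != c_out or stride != 1:
            self.projection = Conv1d(c_in, c_out, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm1d(c_out)
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self.conv1.forward(x, training)
        out = self.bn1.forward(out, training)
        out = self.relu1.forward(out, training)
        out = self.conv2.forward(out, training)
        out = self.bn2.forward(out, training)
        if self.projection is not None:
            shortcut = self.proj_bn.forward(self.projection.forward(x, training), training)
        else:
            shortcut = x
        return self.relu_out.forward(out + shortcut, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu_out.backward(grad)
        gx_main = self.bn2.backward(grad)
        gx_main = self.conv2.backward(gx_main)
        gx_main = self.relu1.backward(gx_main)
        gx_main = self.bn1.backward(gx_main)
        gx_main = self.conv1.backward(gx_main)
        if self.projection is not None:
            gx_short = self.projection.backward(self.proj_bn.backward(grad))
        else:
            gx_short = grad
        return gx_main + gx_short

    def parameters(self) -> List[Dict]:
        params = (
            self.conv1.parameters() + self.bn1.parameters()
            + self.conv2.parameters() + self.bn2.parameters()
        )
        if self.projection is not None:
            params += self.projection.parameters() + self.proj_bn.parameters()
        return params


class Adam:
    """Adam with bias correction; operates in place on layer parameters."""

    def __init__(self, params: List[Dict], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p["grad"][...] = 0.0
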
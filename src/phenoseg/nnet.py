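"""Minimal convolutional network with manual backpropagation.

The per-image refinement stage needs a small, fully deterministic conv net
(a few 3x3 conv layers, each followed by per-channel normalization) trained
with plain SGD + momentum on a pixel-wise cross-entropy loss.  The net is
tiny and trained for a few dozen iterations on a single crop, so an
im2col/BLAS implementation in float32 numpy is entirely adequate and keeps
the dependency surface small.

All state lives in :class:`SegNet`; ``forward`` caches the activations that
``backward`` needs, and ``step`` applies one momentum-SGD update.  Shapes
follow the (H, W, C) convention used by scikit-image.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS = 1e-5


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(H, W, C) -> (H*W, k*k*C) patch matrix, reflect-padded.

    Reflect padding keeps border pixels' features consistent with the
    interior, so image borders do not spawn artificial clusters."""
    p = k // 2
    xp = np.pad(x, ((p, p), (p, p), (0, 0)), mode="reflect")
    win = sliding_window_view(xp, (k, k), axis=(0, 1))  # (H, W, C, k, k)
    h, w, c = x.shape
    return win.transpose(0, 1, 3, 4, 2).reshape(h * w, k * k * c)


class _Conv:
    """3x3 (or 1x1) convolution, zero padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.w = (rng.standard_normal((k * k * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w, _ = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols
        self._shape = (h, w)
        out = cols @ self.w + self.b
        return out.reshape(h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._shape
        c_out = self.w.shape[1]
        dyf = dy.reshape(h * w, c_out).astype(np.float32)
        self.dw = self._cols.T @ dyf
        self.db = dyf.sum(axis=0)
        # Gradient w.r.t. the input: correlate dy with the flipped kernel.
        # (Padding contributions are folded with the same reflect rule; this
        # is exact in the interior and a benign approximation at borders.)
        k = self.k
        c_in = self.w.shape[0] // (k * k)
        w_full = self.w.reshape(k, k, c_in, c_out)
        w_flip = w_full[::-1, ::-1]  # (k, k, c_in, c_out)
        wt = w_flip.transpose(0, 1, 3, 2).reshape(k * k * c_out, c_in)
        dx_cols = _im2col(dyf.reshape(h, w, c_out), k)
        return (dx_cols @ wt).reshape(h, w, c_in)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _BatchNorm:
    """Per-channel normalization over all pixels of the crop (training mode)."""

    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        xf = x.reshape(-1, c)
        self._mu = xf.mean(axis=0)
        self._var = xf.var(axis=0)
        self._istd = 1.0 / np.sqrt(self._var + _EPS)
        self._xhat = (xf - self._mu) * self._istd
        out = self._xhat * self.gamma + self.beta
        return out.reshape(h, w, c).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w, c = dy.shape
        dyf = dy.reshape(-1, c).astype(np.float32)
        n = dyf.shape[0]
        self.dgamma = (dyf * self._xhat).sum(axis=0)
        self.dbeta = dyf.sum(axis=0)
        dxhat = dyf * self.gamma
        dx = (self._istd / n) * (
            n * dxhat
            - dxhat.sum(axis=0)
            - self._xhat * (dxhat * self._xhat).sum(axis=0)
        )
        return dx.reshape(h, w, c)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._m = x > 0
        return np.where(self._m, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._m, dy, 0.0)

    def params(self):
        return []


class SegNet:
    """Pixel classifier: n_layers of [conv -> (ReLU) -> norm], last layer linear.

    The final layer's ``channels`` outputs act as cluster scores; per-pixel
    argmax over them gives the label map.
    """

    def __init__(self, channels: int = 64, n_layers: int = 3, kernel: int = 3,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_in = 3
        for i in range(n_layers):
            last = i == n_layers - 1
            self.layers.append(_Conv(c_in, channels, kernel, rng))
            if not last:
                self.layers.append(_ReLU())
            self.layers.append(_BatchNorm(channels))
            c_in = channels
        self.channels = channels
        self._vel: dict[int, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dscores: np.ndarray) -> None:
        d = dscores
        first = self.layers[0]
        for layer in reversed(self.layers):
            if layer is first:
                # Input gradient is never used; only accumulate dw/db.
                dyf = d.reshape(-1, layer.w.shape[1]).astype(np.float32)
                layer.dw = layer._cols.T @ dyf
                layer.db = dyf.sum(axis=0)
            else:
                d = layer.backward(d)

    def step(self, lr: float, momentum: float) -> None:
        i = 0
        for layer in self.layers:
            for _, p, g in layer.params():
                v = self._vel.get(i)
                if v is None:
                    v = np.zeros_like(p)
                v *= momentum
                v -= lr * g.astype(np.float32)
                self._vel[i] = v
                p += v
                i += 1


def softmax_xent_grad(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy between per-pixel scores and integer labels.

    Returns (loss, dscores); dscores already includes the 1/N factor.
    """
    h, w, c = scores.shape
    s = scores.reshape(-1, c)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s, dtype=np.float32)
    p = e / e.sum(axis=1, keepdims=True)
    lab = labels.reshape(-1)
    n = lab.size
    loss = float(-np.log(p[np.arange(n), lab] + 1e-12).mean())
    d = p
    d[np.arange(n), lab] -= 1.0
    d /= n
    return loss, d.reshape(h, w, c)
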
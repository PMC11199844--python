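"""A compact convolutional network implemented on numpy.

Three 3x3 conv + ReLU + 2x2 max-pool blocks, global average pooling and a
small fully connected head with two softmax outputs.  Convolutions are
computed as im2col matrix products; training uses Adam on softmax
cross-entropy.  Everything is deterministic for a fixed seed and runs on a
single CPU core at desk scale.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CompactCNN", "softmax", "AdamState"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, C*k*k) with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B, H, W, C, k, k)
    b, h, w = x.shape[:3]
    return win.reshape(b * h * w, -1), (b, h, w)


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out

    def forward(self, x):
        cols, (b, h, w) = _im2col(x, self.k)
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.W + self.b
        return y.reshape(b, h, w, self.c_out)

    def backward(self, dy):
        b, h, w, _ = dy.shape
        dy_flat = dy.reshape(-1, self.c_out)
        self.dW = self._cols.T @ dy_flat
        self.db = dy_flat.sum(axis=0)
        # dX: full correlation of dy with spatially flipped kernels
        Wk = self.W.reshape(self.c_in, self.k, self.k, self.c_out)
        Wk = Wk[:, ::-1, ::-1, :]  # flip spatial dims
        Wb = np.ascontiguousarray(Wk.transpose(3, 1, 2, 0)).reshape(self.c_out * self.k * self.k, self.c_in)
        cols, _ = _im2col(dy, self.k)
        dx = (cols @ Wb).reshape(self._in_shape)
        self._cols = None
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return {}


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2, :]
        self._in_shape = x.shape
        xr = xc.reshape(b, h2, 2, w2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # split gradient equally between tied maxima so backward is deterministic
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, dy):
        b, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dxr = self._mask * dy[:, :, None, :, None, :]
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : h2 * 2, : w2 * 2, :] = dxr.reshape(b, h2 * 2, w2 * 2, c)
        return dx

    def params(self):
        return {}


class _AvgPool2:
    """2x2 average pooling, stride 2; odd trailing rows/columns cropped.

    Used as the input stage: mel spectrograms are oversampled relative to
    the texture scale the classifier needs, and halving both axes cuts the
    convolution cost fourfold.
    """

    def forward(self, x):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, : h2 * 2, : w2 * 2, :].reshape(b, h2, 2, w2, 2, c)
        return xr.mean(axis=(2, 4))

    def backward(self, dy):
        b, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        up = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
        dx[:, : h2 * 2, : w2 * 2, :] = up
        return dx

    def params(self):
        return {}


class _GlobalAvgPool:
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        b, h, w, c = self._in_shape
        return np.broadcast_to(dy[:, None, None, :], self._in_shape) / (h * w)

    def params(self):
        return {}


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class AdamState:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self, named_params: dict, named_grads: dict):
        self.t += 1
        for name, p in named_params.items():
            g = named_grads[name].astype(np.float32)
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CompactCNN:
    """Two-class spectrogram classifier.

    Parameters
    ----------
    input_shape
        (n_mel, n_frames, n_channels) of each input tensor.
    channels
        Output channels of the three conv blocks.
    seed
        Seed for weight initialization; identical seeds give identical
        initial parameters.
    """

    def __init__(self, input_shape, channels=(8, 16, 32), hidden=32, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        self.input_shape = tuple(input_shape)
        c_prev = input_shape[2]
        self.layers = [_AvgPool2()]
        for c in channels:
            self.layers += [_Conv(c_prev, c, 3, rng), _ReLU(), _MaxPool2()]
            c_prev = c
        self.layers.append(_GlobalAvgPool())
        self.head = [_Dense(c_prev, hidden, rng), _ReLU(), _Dense(hidden, n_classes, rng)]
        self.n_classes = n_classes

    # -- plumbing ---------------------------------------------------------
    def _all_layers(self):
        return self.layers + self.head

    def named_parameters(self) -> dict:
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for k, v in layer.params().items():
                out[f"layer{i}.{k}"] = v
        return out

    def set_parameters(self, named: dict) -> None:
        for i, layer in enumerate(self._all_layers()):
            for k in layer.params():
                layer.params()[k][:] = named[f"layer{i}.{k}"]

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.named_parameters().values()))

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {x.shape[1:]} != expected {self.input_shape}")
        h = x.astype(np.float32)
        for layer in self._all_layers():
            h = layer.forward(h)
        return h  # logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    def train_step(self, x, y, adam: AdamState) -> tuple[float, float]:
        logits = self.forward(x)
        probs = softmax(logits)
        n = len(x)
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        acc = float((probs.argmax(axis=1) == y).mean())
        dy = probs.copy()
        dy[np.arange(n), y] -= 1.0
        dy /= n
        grad = dy.astype(np.float32)
        for layer in reversed(self._all_layers()):
            grad = layer.backward(grad)
        params, grads = {}, {}
        for i, layer in enumerate(self._all_layers()):
            if hasattr(layer, "grads"):
                for k in layer.params():
                    params[f"layer{i}.{k}"] = layer.params()[k]
                    grads[f"layer{i}.{k}"] = layer.grads()[k]
        adam.step(params, grads)
        return float(loss), acc
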
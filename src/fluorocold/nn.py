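"""Minimal NumPy neural-network layers with exact reverse-mode gradients.

Purpose-built for the spectral sequence classifier in :mod:`fluorocold.models`:
1-D convolutions over the wavelength axis, batch normalization, a gated
recurrent unit (GRU) encoder/decoder, dense layers, and a softmax
cross-entropy head, trained with Adam.  Every layer implements
``forward(x, training)`` and ``backward(dy)``; ``backward`` accumulates
parameter gradients and returns the gradient with respect to the layer input,
which is what both training and gradient-based attribution (Grad-CAM) need.

Conventions
-----------
* Sequence tensors are ``(batch, length, channels)``.
* Conv1D uses 'same' zero padding: for an even kernel k the extra pad column
  goes on the right (pad_left = (k-1)//2).
* GRU is the classic reset-before-matmul form:
  z = sigmoid(xW_z + hU_z + b_z), r = sigmoid(xW_r + hU_r + b_r),
  h~ = tanh(xW_h + (r*h)U_h + b_h), h' = z*h + (1-z)*h~.
  Parameter count per GRU: 3*(n_in*n_h + n_h^2 + n_h).
* All randomness flows through a caller-supplied ``numpy`` Generator, so a
  fixed seed reproduces weights, shuffles and therefore training bit-for-bit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1D", "BatchNorm", "ReLU", "GRU", "RepeatVector",
    "Flatten", "Dense", "Sequential", "Adam", "softmax",
    "softmax_cross_entropy",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = 1e-12
    loss = float(-(onehot * np.log(p + eps)).sum(axis=1).mean())
    return loss, (p - onehot) / len(logits)


class Layer:
    """Base layer: subclasses fill ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        # non-trainable state that must travel with the weights (BN stats)
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1D(Layer):
    """1-D convolution along the sequence axis, 'same' zero padding, stride 1."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, init: str = "he_normal") -> None:
        super().__init__()
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        fan_in = kernel * in_channels
        if init == "he_normal":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, in_channels, filters))
        else:
            limit = np.sqrt(6.0 / (fan_in + filters))
            w = rng.uniform(-limit, limit, size=(kernel, in_channels, filters))
        self.params = {"W": w, "b": np.zeros(filters)}
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp = xp
        L = x.shape[1]
        W = self.params["W"]
        y = np.tensordot(xp[:, 0:L, :], W[0], axes=([2], [0]))
        for t in range(1, self.kernel):
            y += np.tensordot(xp[:, t : t + L, :], W[t], axes=([2], [0]))
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, W = self._xp, self.params["W"]
        L = dy.shape[1]
        dxp = np.zeros_like(xp)
        for t in range(self.kernel):
            self.grads["W"][t] += np.tensordot(xp[:, t : t + L, :], dy, axes=([0, 1], [0, 1]))
            dxp[:, t : t + L, :] += np.tensordot(dy, W[t], axes=([2], [1]))
        self.grads["b"] += dy.sum(axis=(0, 1))
        return dxp[:, self.pad_left : self.pad_left + L, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch and sequence axes."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.buffers = {"running_mean": np.zeros(channels),
                        "running_var": np.ones(channels)}
        self.zero_grad()

    @property
    def running_mean(self) -> np.ndarray:
        return self.buffers["running_mean"]

    @property
    def running_var(self) -> np.ndarray:
        return self.buffers["running_var"]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mean
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mean, var = self.buffers["running_mean"], self.buffers["running_var"]
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._ivar
        self._training = training
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(dy.ndim - 1))
        xhat, ivar = self._xhat, self._ivar
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"]
        if not self._training:
            return dy * g * ivar  # running stats are constants at inference
        n = self._n
        dxhat = dy * g
        return (ivar / n) * (
            n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GRU(Layer):
    """GRU that consumes a ``(B, T, C)`` sequence and emits the final state.

    Kernels use Glorot-uniform init, recurrent kernels orthogonal init,
    biases zero.  ``backward`` runs truncated-free BPTT over all T steps.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden

        def glorot(n_in, n_out):
            limit = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-limit, limit, size=(n_in, n_out))

        def orthogonal(n):
            q, r = np.linalg.qr(rng.normal(size=(n, n)))
            return q * np.sign(np.diag(r))

        self.params = {}
        for gate in ("z", "r", "h"):
            self.params[f"W{gate}"] = glorot(in_dim, hidden)
            self.params[f"U{gate}"] = orthogonal(hidden)
            self.params[f"b{gate}"] = np.zeros(hidden)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        p = self.params
        h = np.zeros((B, self.hidden))
        # input projections are time-independent: hoist them out of the loop
        xz = x @ p["Wz"] + p["bz"]
        xr = x @ p["Wr"] + p["br"]
        xh = x @ p["Wh"] + p["bh"]
        self._h_prev = np.empty((B, T, self.hidden))
        self._z = np.empty_like(self._h_prev)
        self._r = np.empty_like(self._h_prev)
        self._hh = np.empty_like(self._h_prev)
        self._x = x
        for t in range(T):
            z = _sigmoid(xz[:, t, :] + h @ p["Uz"])
            r = _sigmoid(xr[:, t, :] + h @ p["Ur"])
            hh = np.tanh(xh[:, t, :] + (r * h) @ p["Uh"])
            self._h_prev[:, t] = h
            self._z[:, t], self._r[:, t], self._hh[:, t] = z, r, hh
            h = z * h + (1 - z) * hh
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        p, g = self.params, self.grads
        x = self._x
        B, T, C = x.shape
        H = self.hidden
        da_z = np.empty((B, T, H))
        da_r = np.empty((B, T, H))
        da_h = np.empty((B, T, H))
        for t in range(T - 1, -1, -1):
            h_prev, z, r, hh = (self._h_prev[:, t], self._z[:, t],
                                self._r[:, t], self._hh[:, t])
            dah = dh * (1 - z) * (1 - hh**2)
            drh = dah @ p["Uh"].T
            daz = dh * (h_prev - hh) * z * (1 - z)
            dar = drh * h_prev * r * (1 - r)
            da_z[:, t], da_r[:, t], da_h[:, t] = daz, dar, dah
            dh = dh * z + drh * r + daz @ p["Uz"].T + dar @ p["Ur"].T
        # parameter gradients accumulated over all timesteps at once
        xf = x.reshape(B * T, C)
        hf = self._h_prev.reshape(B * T, H)
        rhf = (self._r * self._h_prev).reshape(B * T, H)
        for name, da, rec in (("z", da_z, hf), ("r", da_r, hf), ("h", da_h, rhf)):
            daf = da.reshape(B * T, H)
            g[f"W{name}"] += xf.T @ daf
            g[f"U{name}"] += rec.T @ daf
            g[f"b{name}"] += daf.sum(axis=0)
        return da_z @ p["Wz"].T + da_r @ p["Wr"].T + da_h @ p["Wh"].T


class RepeatVector(Layer):
    """Tile a ``(B, H)`` state into a ``(B, T, H)`` context sequence."""

    def __init__(self, times: int) -> None:
        super().__init__()
        self.times = times

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.repeat(x[:, None, :], self.times, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.sum(axis=1)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.params = {"W": rng.uniform(-limit, limit, size=(in_dim, out_dim)),
                       "b": np.zeros(out_dim)}
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential:
    """Plain layer stack; outputs logits (softmax lives in the loss)."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray, until: int = 0) -> np.ndarray:
        """Backpropagate; stop after layer index ``until`` (input grad of it)."""
        for layer in reversed(self.layers[until:]):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        """Snapshot trainable parameters and stateful buffers (BN statistics)."""
        return [
            {k: v.copy() for k, v in list(layer.params.items()) + list(layer.buffers.items())}
            for layer in self.layers
        ]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k] = w[k].copy()
            for k in layer.buffers:
                layer.buffers[k] = w[k].copy()


class Adam:
    def __init__(self, model: Sequential, lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for layer, m, v in zip(self.model.layers, self.m, self.v):
            for k, p in layer.params.items():
                grad = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * grad
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * grad**2
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
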
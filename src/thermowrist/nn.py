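"""Minimal LSTM network in numpy.

A small, self-contained implementation of a stacked LSTM binary classifier
(two recurrent layers followed by a single sigmoid unit), trained by
backpropagation through time with the Adam update rule. Shapes follow the
(batch, time, features) convention. The backward pass is verified against
finite differences in the test suite.

Gate layout within the fused weight matrices is (input, forget, cell,
output). The forget-gate bias is initialized to 1 so early training does
not erase the cell state.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class LSTMLayer:
    """One LSTM layer; processes a full (B, T, D) batch."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_units = n_units
        H = n_units
        self.W = _glorot(rng, n_in, 4 * H)  # input weights
        self.U = _glorot(rng, H, 4 * H)  # recurrent weights
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.n_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.zeros((B, T, H))
        gates = np.zeros((B, T, 4 * H))
        Cs = np.zeros((B, T, H))
        Cprev = np.zeros((B, T, H))
        for t in range(T):
            z = X[:, t] @ self.W + h @ self.U + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            Cprev[:, t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
            Cs[:, t] = c
            Hs[:, t] = h
        self._cache = (X, Hs, gates, Cs, Cprev)
        return Hs

    def backward(self, dHs: np.ndarray):
        """Given dL/dH for the full output sequence, return (dX, grads)."""
        X, Hs, gates, Cs, Cprev = self._cache
        B, T, _ = X.shape
        H = self.n_units
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = np.tanh(Cs[:, t])
            dh = dHs[:, t] + dh_next
            dc = dh * o * (1.0 - tc**2) + dc_next
            dzi = dc * g * i * (1.0 - i)
            dzf = dc * Cprev[:, t] * f * (1.0 - f)
            dzg = dc * i * (1.0 - g**2)
            dzo = dh * tc * o * (1.0 - o)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            dW += X[:, t].T @ dz
            dU += (Hs[:, t - 1].T @ dz) if t > 0 else 0.0
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dX, [dW, dU, db]


class Dense:
    """Single-unit affine layer (logit head)."""

    def __init__(self, n_in: int, rng: np.random.Generator):
        self.w = _glorot(rng, n_in, 1)[:, 0]
        self.b = np.zeros(1)
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._cache = X
        return X @ self.w + self.b[0]

    def backward(self, dlogit: np.ndarray):
        X = self._cache
        dw = X.T @ dlogit
        db = np.atleast_1d(dlogit.sum())
        dX = np.outer(dlogit, self.w)
        return dX, [dw, db]


class LSTMNetwork:
    """Two stacked LSTM layers + sigmoid head, with input dropout on the
    second layer (one mask per sequence, shared across timesteps)."""

    def __init__(
        self,
        n_features: int,
        n_units: tuple[int, int] = (50, 50),
        dropout: float = 0.2,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.dropout = dropout
        self.layer1 = LSTMLayer(n_features, n_units[0], rng)
        self.layer2 = LSTMLayer(n_units[0], n_units[1], rng)
        self.head = Dense(n_units[1], rng)
        self._mask = None

    @property
    def params(self) -> list[np.ndarray]:
        return self.layer1.params + self.layer2.params + self.head.params

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Return P(y=1) per sequence."""
        H1 = self.layer1.forward(X)
        if training and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            self._mask = (rng.random((X.shape[0], 1, H1.shape[2])) < keep) / keep
            H1 = H1 * self._mask
        else:
            self._mask = None
        H2 = self.layer2.forward(H1)
        self._h_last_T = H2.shape[1]
        logit = self.head.forward(H2[:, -1, :])
        return sigmoid(logit)

    def backward(self, p: np.ndarray, y: np.ndarray, sample_weight: np.ndarray):
        """Gradients of the weighted mean binary cross-entropy."""
        B = y.shape[0]
        dlogit = sample_weight * (p - y) / B
        dh_last, g_head = self.head.backward(dlogit)
        dH2 = np.zeros((B, self._h_last_T, dh_last.shape[1]))
        dH2[:, -1, :] = dh_last
        dH1, g2 = self.layer2.backward(dH2)
        if self._mask is not None:
            dH1 = dH1 * self._mask
        _, g1 = self.layer1.backward(dH1)
        return g1 + g2 + g_head

    @staticmethod
    def loss(p: np.ndarray, y: np.ndarray, sample_weight: np.ndarray) -> float:
        eps = 1e-12
        ll = y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps)
        return float(-(sample_weight * ll).mean())


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
            if norm > self.clip_norm:
                grads = [g * (self.clip_norm / norm) for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
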
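"""Compact numpy neural networks: a fully connected regressor and a dense
diagonal-Gaussian variational autoencoder, both trained with Adam.

These are deliberately small — the models in this package are a
utility-prediction head of at most two 128-unit layers and a
variational autoencoder over 32x32 renders — so full control over
initialization, seeding and training cadence matters more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPRegressor", "Adam"]


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MLPRegressor:
    """Fully connected ReLU network with a linear scalar (or vector) output.

    Parameters
    ----------
    layer_sizes : sequence of int
        [input_dim, hidden..., output_dim].
    seed : int
        Seeds weight initialization and minibatch shuffling.
    zero_init_output : bool
        Initialize the output layer at exactly zero, so an untrained network
        predicts 0 for every input.
    """

    def __init__(self, layer_sizes, seed: int = 0, lr: float = 1e-3,
                 zero_init_output: bool = False, batch_size: int = 32):
        self.layer_sizes = list(layer_sizes)
        if len(self.layer_sizes) < 2 or any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be >= 2 positive integers")
        self.lr = lr
        self.batch_size = batch_size
        self.rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for i, (n_in, n_out) in enumerate(zip(self.layer_sizes, self.layer_sizes[1:])):
            last = i == len(self.layer_sizes) - 2
            if last and zero_init_output:
                self.W.append(np.zeros((n_in, n_out)))
            else:
                self.W.append(_glorot(self.rng, n_in, n_out))
            self.b.append(np.zeros(n_out))
        self.opt = Adam(self.W + self.b, lr=lr)

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = h @ self.W[-1] + self.b[-1]
        return out[:, 0] if out.shape[1] == 1 else out

    def _forward_backward(self, X: np.ndarray, y: np.ndarray):
        acts = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        out = h @ self.W[-1] + self.b[-1]
        err = out - y
        loss = float(np.mean(err ** 2))
        n = X.shape[0]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = 2.0 * err / (n * y.shape[1])
        for li in range(len(self.W) - 1, -1, -1):
            gW[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.W[li].T) * (acts[li] > 0)
        return loss, gW + gb

    def mse(self, X: np.ndarray, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float).reshape(len(np.atleast_2d(X)), -1)
        pred = np.atleast_2d(self.predict(X))
        pred = pred.reshape(y.shape)
        return float(np.mean((pred - y) ** 2))

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int) -> dict:
        """Minibatch Adam on mean-squared error; returns initial/final MSE."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).reshape(X.shape[0], -1)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} != network input dim {self.input_dim}")
        history = {"initial_mse": self.mse(X, y), "final_mse": None}
        n = X.shape[0]
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                _, grads = self._forward_backward(X[idx], y[idx])
                self.opt.step(grads)
        history["final_mse"] = self.mse(X, y)
        return history
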
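"""Minimal NumPy convolutional-network engine for the site classifier.

Implements exactly the architecture family the classifier needs — stacked
[1-D convolution -> ReLU -> max-pool -> dropout] blocks over the encoded
sequence axis, a fully connected ReLU stack, and a single sigmoid output —
with hand-written forward and backward passes. Writing the backward pass
explicitly keeps training (binary cross-entropy, Adam) and input-gradient
attribution on one shared, dependency-light code path.

Convolutions are "valid" (no padding) along the row axis with the four
nucleotide-frequency channels as input channels.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet", "Adam", "sigmoid", "bce_loss"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class ConvNet:
    """Fixed-topology CNN over (rows, 4) encoded inputs.

    ``blocks`` is a list of dicts with keys n_filters, kernel_rows, pool,
    dropout; ``fc_units`` the hidden fully-connected widths. The output is a
    single sigmoid unit. All parameters are He-initialized from ``seed``.
    """

    def __init__(
        self,
        input_rows: int,
        blocks: Sequence[dict],
        fc_units: Sequence[int],
        fc_dropout: float,
        seed: int = 0,
    ) -> None:
        if not blocks:
            raise ValueError("at least one convolution block is required")
        self.blocks = [dict(b) for b in blocks]
        self.fc_units = list(fc_units)
        self.fc_dropout = float(fc_dropout)
        self.input_rows = int(input_rows)

        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        rows, chans = self.input_rows, 4
        for i, b in enumerate(self.blocks):
            k, f, p = b["kernel_rows"], b["n_filters"], b["pool"]
            if not (0.0 <= b["dropout"] < 1.0):
                raise ValueError(f"block {i}: dropout must be in [0, 1)")
            if k > rows:
                raise ValueError(
                    f"block {i}: kernel_rows={k} exceeds remaining length {rows}"
                )
            fan_in = k * chans
            self.params[f"conv{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(f, k, chans)
            )
            self.params[f"conv{i}_b"] = np.zeros(f)
            rows = rows - k + 1
            rows = rows // p
            if rows < 1:
                raise ValueError(f"block {i}: pooling reduces length below 1")
            chans = f
        self.flat_dim = rows * chans
        dim = self.flat_dim
        for j, u in enumerate(self.fc_units):
            self.params[f"fc{j}_W"] = rng.normal(0.0, np.sqrt(2.0 / dim), size=(dim, u))
            self.params[f"fc{j}_b"] = np.zeros(u)
            dim = u
        self.params["out_W"] = rng.normal(0.0, np.sqrt(1.0 / dim), size=(dim, 1))
        self.params["out_b"] = np.zeros(1)

    # -- forward -----------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.input_rows or X.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (N, {self.input_rows}, 4), got {X.shape}"
            )
        return X

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list]:
        """Return (logits, cache). Dropout is active only when training."""
        X = self._check_input(X)
        if training and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        cache: list = [("input", X)]
        A = X
        for i, b in enumerate(self.blocks):
            W, bias = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            k = b["kernel_rows"]
            Aw = sliding_window_view(A, k, axis=1)  # (N, out, C, k)
            Z = np.einsum("nlck,fkc->nlf", Aw, W, optimize=True) + bias
            relu_mask = Z > 0
            A1 = Z * relu_mask
            p = b["pool"]
            n, L, f = A1.shape
            Lp = L // p
            A1t = A1[:, : Lp * p, :].reshape(n, Lp, p, f)
            arg = A1t.argmax(axis=2)
            P = np.take_along_axis(A1t, arg[:, :, None, :], axis=2)[:, :, 0, :]
            if training and b["dropout"] > 0:
                mask = (rng.random(P.shape) >= b["dropout"]) / (1.0 - b["dropout"])
                D = P * mask
            else:
                mask = None
                D = P
            cache.append(("block", A, relu_mask, arg, A1.shape, mask, i))
            A = D
        flat = A.reshape(A.shape[0], -1)
        cache.append(("flatten", A.shape))
        H = flat
        for j in range(len(self.fc_units)):
            W, bias = self.params[f"fc{j}_W"], self.params[f"fc{j}_b"]
            Z = H @ W + bias
            relu_mask = Z > 0
            A2 = Z * relu_mask
            if training and self.fc_dropout > 0:
                mask = (rng.random(A2.shape) >= self.fc_dropout) / (1.0 - self.fc_dropout)
                D2 = A2 * mask
            else:
                mask = None
                D2 = A2
            cache.append(("fc", H, relu_mask, mask, j))
            H = D2
        logits = (H @ self.params["out_W"] + self.params["out_b"])[:, 0]
        cache.append(("out", H))
        return logits, cache

    # -- backward ----------------------------------------------------------

    def backward(
        self, cache: list, dlogits: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backprop d(loss)/d(logits) through the cached forward pass.

        Returns (parameter gradients, gradient w.r.t. the input matrix).
        """
        grads: dict[str, np.ndarray] = {}
        idx = len(cache) - 1
        tag, H = cache[idx]
        assert tag == "out"
        dH = dlogits[:, None] @ self.params["out_W"].T
        grads["out_W"] = H.T @ dlogits[:, None]
        grads["out_b"] = np.array([dlogits.sum()])
        idx -= 1
        while cache[idx][0] == "fc":
            _, Hin, relu_mask, mask, j = cache[idx]
            if mask is not None:
                dH = dH * mask
            dZ = dH * relu_mask
            grads[f"fc{j}_W"] = Hin.T @ dZ
            grads[f"fc{j}_b"] = dZ.sum(axis=0)
            dH = dZ @ self.params[f"fc{j}_W"].T
            idx -= 1
        tag, pooled_shape = cache[idx]
        assert tag == "flatten"
        dA = dH.reshape(pooled_shape)
        idx -= 1
        while cache[idx][0] == "block":
            _, Ain, relu_mask, arg, conv_shape, mask, i = cache[idx]
            b = self.blocks[i]
            k, p = b["kernel_rows"], b["pool"]
            if mask is not None:
                dA = dA * mask
            n, L, f = conv_shape
            Lp = L // p
            dA1t = np.zeros((n, Lp, p, f))
            np.put_along_axis(dA1t, arg[:, :, None, :], dA[:, :, None, :], axis=2)
            dA1 = np.zeros((n, L, f))
            dA1[:, : Lp * p, :] = dA1t.reshape(n, Lp * p, f)
            dZ = dA1 * relu_mask
            W = self.params[f"conv{i}_W"]
            Aw = sliding_window_view(Ain, k, axis=1)
            grads[f"conv{i}_W"] = np.einsum("nlck,nlf->fkc", Aw, dZ, optimize=True)
            grads[f"conv{i}_b"] = dZ.sum(axis=(0, 1))
            dAin = np.zeros_like(Ain)
            out_len = Ain.shape[1] - k + 1
            for j in range(k):
                dAin[:, j : j + out_len, :] += np.einsum(
                    "nlf,fc->nlc", dZ, W[:, j, :], optimize=True
                )
            dA = dAin
            idx -= 1
        return grads, dA

    # -- inference-time conveniences --------------------------------------

    def predict_logit(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X, training=False)
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.predict_logit(X))

    def input_gradient(self, X: np.ndarray, wrt: str = "prob") -> np.ndarray:
        """Gradient of the output (sigmoid prob, or pre-sigmoid logit) w.r.t. X."""
        X = self._check_input(X)
        logits, cache = self.forward(X, training=False)
        if wrt == "prob":
            p = sigmoid(logits)
            dlogits = p * (1.0 - p)
        elif wrt == "logit":
            dlogits = np.ones_like(logits)
        else:
            raise ValueError("wrt must be 'prob' or 'logit'")
        _, dX = self.backward(cache, dlogits)
        return dX

    def first_conv_activations(self, X: np.ndarray) -> np.ndarray:
        """Post-ReLU first-layer activations, shape (N, out_len, n_filters)."""
        X = self._check_input(X)
        W, bias = self.params["conv0_W"], self.params["conv0_b"]
        k = self.blocks[0]["kernel_rows"]
        Aw = sliding_window_view(X, k, axis=1)
        Z = np.einsum("nlck,fkc->nlf", Aw, W, optimize=True) + bias
        return np.maximum(Z, 0.0)

    @contextmanager
    def filters_nullified(self, filter_indices: Sequence[int]) -> Iterator[None]:
        """Temporarily zero first-layer filters (weights and bias); restores on exit."""
        n_filters = self.params["conv0_W"].shape[0]
        for f in filter_indices:
            if not (0 <= f < n_filters):
                raise ValueError(f"filter index {f} out of range [0, {n_filters})")
        W_save = self.params["conv0_W"].copy()
        b_save = self.params["conv0_b"].copy()
        try:
            for f in filter_indices:
                self.params["conv0_W"][f] = 0.0
                self.params["conv0_b"][f] = 0.0
            yield
        finally:
            self.params["conv0_W"] = W_save
            self.params["conv0_b"] = b_save

    # -- (de)serialization -------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            new = np.asarray(weights[k], dtype=float)
            if new.shape != v.shape:
                raise ValueError(f"weight {k}: shape {new.shape} != {v.shape}")
            self.params[k] = new.copy()


class Adam:
    """Adam optimizer over a named-parameter dict."""

    def __init__(
        self,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
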
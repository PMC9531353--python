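"""NumPy implementation of the sequence classifier network.

Layer stack (defaults in parentheses):

    embedding(65 -> 64) -> batch norm over the 64 embedding features
    -> bidirectional LSTM(64 -> 128 per direction)
    -> flatten(298 x 256 -> 76288) -> FC1(-> 128) + leaky ReLU
    -> FC2(-> 1) + sigmoid

Forward and backward passes are written against exact analytic
gradients (verified by finite differences in the test suite); training
uses Adam.  Everything is plain NumPy so results are deterministic for a
fixed seed on any machine.

Gate layout in the fused LSTM weight matrices is (input, forget, cell,
output) along the last axis.  Batch-norm statistics are pooled over the
batch and sequence-position axes, the standard choice for
(batch, position, feature) tensors.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class SeqvecNet:
    """The classifier network with explicit forward/backward passes.

    Parameters
    ----------
    vocab_size, embed_dim, hidden_dim, seq_len, fc1_dim, leaky_slope
        Architecture dimensions; see :class:`promoterlstm.model.ModelConfig`.
    seed
        Seeds the parameter initialization.
    dtype
        float32 for speed (default); float64 for gradient checking.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(
        self,
        vocab_size: int = 65,
        embed_dim: int = 64,
        hidden_dim: int = 128,
        seq_len: int = 298,
        fc1_dim: int = 128,
        leaky_slope: float = 0.01,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if min(vocab_size, embed_dim, hidden_dim, seq_len, fc1_dim) < 1:
            raise ValueError("all architecture dimensions must be positive")
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.seq_len = seq_len
        self.fc1_dim = fc1_dim
        self.leaky_slope = leaky_slope
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        E, H, F = embed_dim, hidden_dim, fc1_dim
        flat = seq_len * 2 * H

        p: Dict[str, np.ndarray] = {}
        p["emb"] = rng.standard_normal((vocab_size, E)).astype(dtype)
        p["bn_gamma"] = np.ones(E, dtype=dtype)
        p["bn_beta"] = np.zeros(E, dtype=dtype)
        for d in ("f", "b"):  # forward / backward direction
            p[f"W_{d}"] = _glorot(rng, E, 4 * H, dtype)
            p[f"U_{d}"] = _glorot(rng, H, 4 * H, dtype)
            bias = np.zeros(4 * H, dtype=dtype)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            p[f"b_{d}"] = bias
        p["W1"] = _glorot(rng, flat, F, dtype)
        p["b1"] = np.zeros(F, dtype=dtype)
        p["W2"] = _glorot(rng, F, 1, dtype)
        p["b2"] = np.zeros(1, dtype=dtype)
        self.params = p
        self.running_mean = np.zeros(E, dtype=np.float64)
        self.running_var = np.ones(E, dtype=np.float64)
        self._cache: Optional[dict] = None

    # ------------------------------------------------------------------
    @property
    def flattened_dim(self) -> int:
        return self.seq_len * 2 * self.hidden_dim

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def param_names(self) -> List[str]:
        return sorted(self.params)

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=self.dtype)
        self.running_mean = np.asarray(state["running_mean"], dtype=np.float64)
        self.running_var = np.asarray(state["running_var"], dtype=np.float64)

    # ------------------------------------------------------------------
    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.seq_len:
            raise ValueError(
                f"expected input of shape (n, {self.seq_len}), got {X.shape}"
            )
        if not np.issubdtype(X.dtype, np.integer):
            raise ValueError("input must be an integer index matrix")
        if X.min(initial=0) < 0 or X.max(initial=0) >= self.vocab_size:
            raise ValueError(
                f"indices must lie in [0, {self.vocab_size - 1}]"
            )
        return X

    def _lstm_forward(
        self, A: np.ndarray, direction: str
    ) -> Tuple[np.ndarray, dict]:
        """Run one LSTM direction over A (n, T, E); returns H (n, T, Hd)."""
        n, T, _ = A.shape
        Hd = self.hidden_dim
        W = self.params[f"W_{direction}"]
        U = self.params[f"U_{direction}"]
        b = self.params[f"b_{direction}"]
        steps = range(T) if direction == "f" else range(T - 1, -1, -1)
        # input contribution for all timesteps in one matmul
        Zx = A.reshape(n * T, -1) @ W
        Zx = Zx.reshape(n, T, 4 * Hd)
        h = np.zeros((n, Hd), dtype=self.dtype)
        c = np.zeros((n, Hd), dtype=self.dtype)
        Hout = np.zeros((n, T, Hd), dtype=self.dtype)
        gates = np.zeros((n, T, 4 * Hd), dtype=self.dtype)  # i, f, g, o post-activation
        cells = np.zeros((n, T, Hd), dtype=self.dtype)
        for t in steps:
            z = Zx[:, t] + h @ U + b
            i = sigmoid(z[:, :Hd])
            f = sigmoid(z[:, Hd : 2 * Hd])
            g = np.tanh(z[:, 2 * Hd : 3 * Hd])
            o = sigmoid(z[:, 3 * Hd :])
            c = f * c + i * g
            h = o * np.tanh(c)
            Hout[:, t] = h
            gates[:, t, :Hd] = i
            gates[:, t, Hd : 2 * Hd] = f
            gates[:, t, 2 * Hd : 3 * Hd] = g
            gates[:, t, 3 * Hd :] = o
            cells[:, t] = c
        cache = {"A": A, "gates": gates, "cells": cells, "H": Hout, "steps": list(steps)}
        return Hout, cache

    def _lstm_backward(
        self, dH: np.ndarray, cache: dict, direction: str, grads: Dict[str, np.ndarray]
    ) -> np.ndarray:
        """Backprop one direction; accumulates weight grads, returns dA."""
        A, gates, cells, steps = cache["A"], cache["gates"], cache["cells"], cache["steps"]
        n, T, _ = A.shape
        Hd = self.hidden_dim
        W = self.params[f"W_{direction}"]
        U = self.params[f"U_{direction}"]
        dZx = np.zeros((n, T, 4 * Hd), dtype=self.dtype)
        dU = np.zeros_like(U)
        db = np.zeros(4 * Hd, dtype=self.dtype)
        dh_next = np.zeros((n, Hd), dtype=self.dtype)
        dc_next = np.zeros((n, Hd), dtype=self.dtype)
        zero = np.zeros((n, Hd), dtype=self.dtype)
        for idx in range(len(steps) - 1, -1, -1):
            t = steps[idx]
            t_prev = steps[idx - 1] if idx > 0 else None
            i = gates[:, t, :Hd]
            f = gates[:, t, Hd : 2 * Hd]
            g = gates[:, t, 2 * Hd : 3 * Hd]
            o = gates[:, t, 3 * Hd :]
            c = cells[:, t]
            c_prev = cells[:, t_prev] if t_prev is not None else zero
            h_prev = cache["H"][:, t_prev] if t_prev is not None else zero
            tc = np.tanh(c)
            dh = dH[:, t] + dh_next
            do = dh * tc * o * (1.0 - o)
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g * i * (1.0 - i)
            df = dc * c_prev * f * (1.0 - f)
            dg = dc * i * (1.0 - g * g)
            dc_next = dc * f
            dz = np.concatenate([di, df, dg, do], axis=1)
            dZx[:, t] = dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ U.T
        dZx_flat = dZx.reshape(n * T, 4 * Hd)
        grads[f"W_{direction}"] = A.reshape(n * T, -1).T @ dZx_flat
        grads[f"U_{direction}"] = dU
        grads[f"b_{direction}"] = db
        return (dZx_flat @ W.T).reshape(n, T, -1)

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Return the pre-sigmoid logits, shape (n,).

        In training mode batch-norm uses batch statistics, updates the
        running averages, and intermediate activations are cached for
        :meth:`backward`.
        """
        X = self._check_input(X)
        p = self.params
        n = X.shape[0]
        E0 = p["emb"][X]  # (n, T, E)
        if training:
            mu = E0.mean(axis=(0, 1))
            var = E0.var(axis=(0, 1))
            m = n * self.seq_len
            # unbiased variance for the running average, as torch does
            unbiased = var * m / max(m - 1, 1)
            self.running_mean = (
                (1 - self.BN_MOMENTUM) * self.running_mean + self.BN_MOMENTUM * mu
            )
            self.running_var = (
                (1 - self.BN_MOMENTUM) * self.running_var + self.BN_MOMENTUM * unbiased
            )
        else:
            mu = self.running_mean.astype(self.dtype)
            var = self.running_var.astype(self.dtype)
        inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
        xhat = (E0 - mu) * inv_std
        A = (p["bn_gamma"] * xhat + p["bn_beta"]).astype(self.dtype)

        Hf, cache_f = self._lstm_forward(A, "f")
        Hb, cache_b = self._lstm_forward(A, "b")
        Hcat = np.concatenate([Hf, Hb], axis=2)  # (n, T, 2H)
        flat = Hcat.reshape(n, -1)
        Z1 = flat @ p["W1"] + p["b1"]
        A1 = np.where(Z1 > 0, Z1, self.leaky_slope * Z1)
        logits = (A1 @ p["W2"] + p["b2"]).ravel()
        if training:
            self._cache = {
                "X": X,
                "xhat": xhat,
                "inv_std": inv_std,
                "cache_f": cache_f,
                "cache_b": cache_b,
                "flat": flat,
                "Z1": Z1,
                "A1": A1,
            }
        else:
            self._cache = None
        return logits

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode probabilities in (0, 1), chunked to bound memory."""
        X = self._check_input(X)
        out = np.empty(X.shape[0], dtype=np.float64)
        for start in range(0, X.shape[0], batch_size):
            chunk = X[start : start + batch_size]
            out[start : start + chunk.shape[0]] = sigmoid(
                self.forward(chunk, training=False).astype(np.float64)
            )
        return out

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter.

        ``dlogits`` is dLoss/dlogit, shape (n,); requires a preceding
        training-mode forward pass.
        """
        if self._cache is None:
            raise RuntimeError("backward requires a training-mode forward pass")
        c = self._cache
        p = self.params
        n = c["X"].shape[0]
        grads: Dict[str, np.ndarray] = {}

        dlogits = dlogits.reshape(n, 1).astype(self.dtype)
        grads["W2"] = c["A1"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        dA1 = dlogits @ p["W2"].T
        dZ1 = dA1 * np.where(c["Z1"] > 0, 1.0, self.leaky_slope).astype(self.dtype)
        grads["W1"] = c["flat"].T @ dZ1
        grads["b1"] = dZ1.sum(axis=0)
        dflat = dZ1 @ p["W1"].T
        dHcat = dflat.reshape(n, self.seq_len, 2 * self.hidden_dim)
        dA = self._lstm_backward(dHcat[:, :, : self.hidden_dim], c["cache_f"], "f", grads)
        dA += self._lstm_backward(dHcat[:, :, self.hidden_dim :], c["cache_b"], "b", grads)

        # batch norm backward, statistics pooled over (batch, position)
        xhat, inv_std = c["xhat"], c["inv_std"]
        m = n * self.seq_len
        grads["bn_gamma"] = (dA * xhat).sum(axis=(0, 1))
        grads["bn_beta"] = dA.sum(axis=(0, 1))
        dxhat = dA * p["bn_gamma"]
        dE0 = (
            inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        ).astype(self.dtype)

        demb = np.zeros_like(p["emb"])
        np.add.at(demb, c["X"].ravel(), dE0.reshape(-1, self.embed_dim))
        grads["emb"] = demb
        self._cache = None
        return grads


def bce_from_logits(
    logits: np.ndarray, y: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    Computed directly from logits for numerical stability:
    ``softplus(z) - y*z`` per sample; the gradient is ``(p - y)/n``.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


class Adam:
    """Adam optimizer with bias correction and optional gradient clipping."""

    def __init__(
        self,
        net: SeqvecNet,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: Optional[float] = 5.0,
    ) -> None:
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in net.params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in net.params.items()}

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values())
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(np.float64)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            update = (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            self.net.params[k] = (
                self.net.params[k].astype(np.float64) - self.lr * update
            ).astype(self.net.dtype)
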
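"""Minimal LSTM sequence classifier in numpy.

A single-layer LSTM over right-aligned sequence tensors, with a softmax
read-out from the final hidden state, class-weighted cross-entropy loss,
Adam, global-norm gradient clipping and best-epoch early stopping. Small on
purpose: the sequences are short (28 steps) and desk-scale cohorts need no
GPU. Deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMClassifier"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class LSTMClassifier:
    """3-class (configurable) LSTM classifier on (N, T, D) tensors."""

    def __init__(
        self,
        hidden: int = 16,
        n_classes: int = 3,
        epochs: int = 8,
        batch_size: int = 256,
        lr: float = 0.01,
        clip_norm: float = 5.0,
        seed: int = 0,
    ) -> None:
        self.hidden = hidden
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.clip_norm = clip_norm
        self.seed = seed
        self.params_: dict[str, np.ndarray] | None = None
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None

    # -- standardization (value channels only would need caller knowledge;
    # masks are 0/1 so z-scoring them is harmless and keeps this generic)
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def _init_params(self, D: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        H, C = self.hidden, self.n_classes
        s = 1.0 / np.sqrt(H)
        p = {
            "Wx": rng.uniform(-s, s, (D, 4 * H)),
            "Wh": rng.uniform(-s, s, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wo": rng.uniform(-s, s, (H, C)),
            "bo": np.zeros(C),
        }
        p["b"][H:2 * H] = 1.0  # forget-gate bias init
        return p

    def _forward(self, X: np.ndarray, params: dict, cache: bool = False):
        N, T, D = X.shape
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        steps = []
        for t in range(T):
            z = X[:, t, :] @ params["Wx"] + h @ params["Wh"] + params["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            if cache:
                steps.append((h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        logits = h @ params["Wo"] + params["bo"]
        return (logits, h, steps) if cache else logits

    def _backward(self, X, y_onehot, w, params):
        """Gradients of the weighted cross-entropy; returns (loss, grads)."""
        N, T, D = X.shape
        H = self.hidden
        logits, hT, steps = self._forward(X, params, cache=True)
        probs = _softmax(logits)
        wsum = w.sum()
        loss = -(w * np.log((probs * y_onehot).sum(axis=1) + 1e-12)).sum() / wsum

        dlogits = (probs - y_onehot) * (w / wsum)[:, None]
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        grads["Wo"] = hT.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)

        dh = dlogits @ params["Wo"].T
        dc = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new = steps[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2),
                 do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += X[:, t, :].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ params["Wh"].T
            dc = dc * f
        return loss, grads

    def fit(self, X: np.ndarray, y: np.ndarray, class_weight: dict | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit")
        C = len(self.classes_)
        self.n_classes = C

        self.mean_ = X.mean(axis=(0, 1), keepdims=True)
        self.scale_ = X.std(axis=(0, 1), keepdims=True)
        self.scale_[self.scale_ < 1e-8] = 1.0
        Xs = self._standardize(X)

        if class_weight is None:
            counts = np.bincount(y_idx, minlength=C)
            cw = len(y) / (C * np.maximum(counts, 1))
        else:
            cw = np.array([class_weight.get(cls, 1.0) for cls in self.classes_])
        w = cw[y_idx]
        onehot = np.eye(C)[y_idx]

        rng = np.random.default_rng(self.seed)
        params = self._init_params(X.shape[2], rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, best_params = np.inf, None

        N = len(Xs)
        for _ in range(self.epochs):
            order = rng.permutation(N)
            epoch_loss = 0.0
            for start in range(0, N, self.batch_size):
                idx = order[start:start + self.batch_size]
                loss, grads = self._backward(Xs[idx], onehot[idx], w[idx], params)
                epoch_loss += loss * len(idx)
                gnorm = np.sqrt(sum((g**2).sum() for g in grads.values()))
                if gnorm > self.clip_norm:
                    for k in grads:
                        grads[k] *= self.clip_norm / gnorm
                step += 1
                for k in params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1**step)
                    vh = v[k] / (1 - b2**step)
                    params[k] = params[k] - self.lr * mh / (np.sqrt(vh) + eps)
            epoch_loss /= N
            if epoch_loss < best_loss:
                best_loss = epoch_loss
                best_params = {k: p.copy() for k, p in params.items()}
        self.params_ = best_params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        Xs = self._standardize(np.asarray(X, dtype=float))
        out = np.empty((len(Xs), self.n_classes))
        for start in range(0, len(Xs), 4096):
            out[start:start + 4096] = _softmax(
                self._forward(Xs[start:start + 4096], self.params_)
            )
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
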
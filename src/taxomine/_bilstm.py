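"""Bidirectional LSTM sequence classifier in plain numpy.

The network mirrors the three-layer relation classifier: a learned word
embedding (token embedding concatenated with a learned dependency-label /
direction embedding per path step), a bidirectional LSTM over the shortest
dependency path, and a dense hidden layer feeding a two-way softmax.

Everything is float64 and driven by a single seeded Generator, so a fixed
seed reproduces training bit-for-bit on any platform: parameter
initialization, minibatch order and dropout masks all come from that one
stream, and the math is ordinary dense numpy with no threading
nondeterminism at these sizes.

Shapes: B batch, T padded path length, H lstm units, d = token + label
embedding width. Gate layout in the fused matrices is [i, f, g, o].
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class BiLSTMNet:
    """Embedding -> BiLSTM -> ReLU hidden -> softmax(2)."""

    def __init__(
        self,
        n_tokens: int,
        n_labels: int,
        token_dim: int,
        label_dim: int,
        lstm_units: int,
        hidden_units: int,
        rng: np.random.Generator,
    ) -> None:
        d = token_dim + label_dim
        h = lstm_units
        p: dict[str, np.ndarray] = {
            "Et": rng.uniform(-0.1, 0.1, size=(n_tokens, token_dim)),
            "El": rng.uniform(-0.1, 0.1, size=(n_labels, label_dim)),
            "Whid": _glorot(rng, 2 * h, hidden_units),
            "bhid": np.zeros(hidden_units),
            "Wout": _glorot(rng, hidden_units, 2),
            "bout": np.zeros(2),
        }
        for direction in ("f", "b"):
            p[f"Wx_{direction}"] = _glorot(rng, d, 4 * h)
            p[f"Wh_{direction}"] = _glorot(rng, h, 4 * h)
            bias = np.zeros(4 * h)
            bias[h : 2 * h] = 1.0  # forget-gate bias: remember by default
            p[f"b_{direction}"] = bias
        self.params = p
        self.token_dim = token_dim
        self.label_dim = label_dim
        self.lstm_units = lstm_units
        self.hidden_units = hidden_units

    # -- LSTM over one direction -------------------------------------------

    def _lstm_forward(self, X: np.ndarray, mask: np.ndarray, direction: str):
        Wx = self.params[f"Wx_{direction}"]
        Wh = self.params[f"Wh_{direction}"]
        b = self.params[f"b_{direction}"]
        B, T, _ = X.shape
        h_units = self.lstm_units
        h = np.zeros((B, h_units))
        c = np.zeros((B, h_units))
        steps = []
        for t in range(T):
            a = X[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(a[:, :h_units])
            f = _sigmoid(a[:, h_units : 2 * h_units])
            g = np.tanh(a[:, 2 * h_units : 3 * h_units])
            o = _sigmoid(a[:, 3 * h_units :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t : t + 1]
            steps.append((h, c, i, f, g, o, c_new, tc, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        return h, steps

    def _lstm_backward(
        self,
        dh_final: np.ndarray,
        X: np.ndarray,
        steps: list,
        direction: str,
    ):
        Wx = self.params[f"Wx_{direction}"]
        Wh = self.params[f"Wh_{direction}"]
        h_units = self.lstm_units
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params[f"b_{direction}"])
        dX = np.zeros_like(X)
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for t in range(len(steps) - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc, m = steps[t]
            dh_new = dh * m
            dh_skip = dh * (1.0 - m)
            dc_new = dc * m
            dc_skip = dc * (1.0 - m)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
            df = dc_new * c_prev
            dc_prev = dc_new * f
            di = dc_new * g
            dg = dc_new * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ Wx.T
            dh = da @ Wh.T + dh_skip
            dc = dc_prev + dc_skip
        return dX, dWx, dWh, db

    # -- full network -------------------------------------------------------

    @staticmethod
    def _reverse_index(mask: np.ndarray) -> np.ndarray:
        """Per-row index that reverses the valid (left-aligned) prefix."""
        B, T = mask.shape
        lengths = mask.sum(axis=1).astype(int)
        idx = np.broadcast_to(np.arange(T), (B, T))
        return np.where(idx < lengths[:, None], lengths[:, None] - 1 - idx, idx)

    def forward(
        self,
        tok_ids: np.ndarray,
        lab_ids: np.ndarray,
        mask: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        p = self.params
        X = np.concatenate([p["Et"][tok_ids], p["El"][lab_ids]], axis=2)
        B = X.shape[0]
        rows = np.arange(B)[:, None]
        rev = self._reverse_index(mask)
        X_rev = X[rows, rev]
        hf, steps_f = self._lstm_forward(X, mask, "f")
        hb, steps_b = self._lstm_forward(X_rev, mask, "b")
        z0 = np.concatenate([hf, hb], axis=1)
        a1 = z0 @ p["Whid"] + p["bhid"]
        h1 = np.maximum(a1, 0.0)
        if dropout > 0.0 and rng is not None:
            keep = (rng.random(h1.shape) >= dropout) / (1.0 - dropout)
        else:
            keep = None
        h1d = h1 if keep is None else h1 * keep
        logits = h1d @ p["Wout"] + p["bout"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(shifted)
        probs = ex / ex.sum(axis=1, keepdims=True)
        cache = (X, X_rev, rev, steps_f, steps_b, z0, a1, keep, h1d, probs, tok_ids, lab_ids)
        return probs, cache

    def loss_and_grads(self, cache, y: np.ndarray):
        """Mean cross-entropy and gradients for a forward cache and labels y."""
        p = self.params
        (X, X_rev, rev, steps_f, steps_b, z0, a1, keep, h1d, probs, tok_ids, lab_ids) = cache
        B = probs.shape[0]
        rows_flat = np.arange(B)
        eps = 1e-12
        loss = -np.mean(np.log(probs[rows_flat, y] + eps))
        dlogits = probs.copy()
        dlogits[rows_flat, y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        grads["Wout"] = h1d.T @ dlogits
        grads["bout"] = dlogits.sum(axis=0)
        dh1d = dlogits @ p["Wout"].T
        dh1 = dh1d if keep is None else dh1d * keep
        da1 = dh1 * (a1 > 0)
        grads["Whid"] = z0.T @ da1
        grads["bhid"] = da1.sum(axis=0)
        dz0 = da1 @ p["Whid"].T
        h = self.lstm_units
        dX_f, dWx_f, dWh_f, db_f = self._lstm_backward(dz0[:, :h], X, steps_f, "f")
        dX_rev, dWx_b, dWh_b, db_b = self._lstm_backward(dz0[:, h:], X_rev, steps_b, "b")
        grads["Wx_f"], grads["Wh_f"], grads["b_f"] = dWx_f, dWh_f, db_f
        grads["Wx_b"], grads["Wh_b"], grads["b_b"] = dWx_b, dWh_b, db_b
        rows = np.arange(X.shape[0])[:, None]
        dX_b = np.empty_like(dX_rev)
        dX_b[rows, rev] = dX_rev  # rev is a per-row permutation
        dX = dX_f + dX_b
        dEt = np.zeros_like(p["Et"])
        dEl = np.zeros_like(p["El"])
        np.add.at(dEt, tok_ids, dX[:, :, : self.token_dim])
        np.add.at(dEl, lab_ids, dX[:, :, self.token_dim :])
        grads["Et"], grads["El"] = dEt, dEl
        return loss, grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
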
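"""A single-layer GRU sequence classifier in plain numpy.

Architecture: GRU over the per-token feature rows (all-zero rows are
treated as padding and freeze the hidden state), then dropout on the
final hidden state, then one dense unit with a sigmoid output.  Trained
by mini-batch gradient descent (Adam) on binary cross-entropy with
through-time backpropagation and global-norm gradient clipping.

The auxiliary input adapter optionally rescales the three trailing
whole-post features of each token row (polarity, subjectivity, hour) to
[0, 1] so the raw 0-23 hour does not dominate the word-vector scale; the
stored tensor itself is never modified.
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


class GRUClassifier:
    """GRU + dropout + dense sigmoid head.

    Parameters are stored in a flat dict; ``W``/``U``/``b`` stack the
    update (z), reset (r) and candidate (h) gates along the second axis.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_units: int,
        dropout: float,
        seed: int,
        normalize_aux: bool = True,
    ):
        self.input_dim = input_dim
        self.hidden = hidden_units
        self.dropout = dropout
        self.normalize_aux = normalize_aux
        rng = np.random.default_rng(seed)
        H, F = hidden_units, input_dim

        def glorot(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out))

        self.params: dict[str, np.ndarray] = {
            "W": glorot(F, 3 * H),
            "U": glorot(H, 3 * H),
            "b": np.zeros(3 * H),
            "Wo": glorot(H, 1),
            "bo": np.zeros(1),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- input adapter -------------------------------------------------
    def _adapt(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (adapted X, padding mask).  Padding = all-zero row,
        judged on the raw tensor before any rescaling."""
        X = np.asarray(X, dtype=np.float64)
        mask = (np.abs(X).sum(axis=2) > 0).astype(np.float64)  # (B, T)
        if self.normalize_aux:
            X = X.copy()
            X[..., -3] = (X[..., -3] + 1.0) / 2.0  # polarity -> [0, 1]
            X[..., -1] = X[..., -1] / 23.0  # hour -> [0, 1]
            X *= mask[..., None]  # keep padding rows exactly zero
        return X, mask

    # -- forward -------------------------------------------------------
    def _forward(self, X: np.ndarray, mask: np.ndarray):
        B, T, _ = X.shape
        H = self.hidden
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H))
        cache = []
        for t in range(T):
            x_t = X[:, t, :]
            m = mask[:, t][:, None]
            a = x_t @ W + b
            az = a[:, :H] + h @ U[:, :H]
            ar = a[:, H : 2 * H] + h @ U[:, H : 2 * H]
            z = _sigmoid(az)
            r = _sigmoid(ar)
            rh = r * h
            ah = a[:, 2 * H :] + rh @ U[:, 2 * H :]
            c = np.tanh(ah)
            h_new = (1.0 - z) * h + z * c
            h_next = m * h_new + (1.0 - m) * h
            cache.append((x_t, h, z, r, c, rh, m))
            h = h_next
        return h, cache

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities of the positive (sleep-deprived) class."""
        Xa, mask = self._adapt(X)
        h, _ = self._forward(Xa, mask)
        return _sigmoid(h @ self.params["Wo"] + self.params["bo"]).ravel()

    # -- loss + gradients ---------------------------------------------
    def loss_and_grads(self, X, y, rng: np.random.Generator):
        """Mean BCE loss and parameter gradients for one mini-batch."""
        Xa, mask = self._adapt(X)
        B = Xa.shape[0]
        H = self.hidden
        h, cache = self._forward(Xa, mask)

        if self.dropout > 0.0:
            keep = 1.0 - self.dropout
            dmask = (rng.random(h.shape) < keep) / keep
        else:
            dmask = np.ones_like(h)
        hd = h * dmask
        logits = (hd @ self.params["Wo"] + self.params["bo"]).ravel()
        y = np.asarray(y, dtype=np.float64)
        loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))

        dlogit = (_sigmoid(logits) - y)[:, None] / B
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wo"] = hd.T @ dlogit
        grads["bo"] = dlogit.sum(axis=0)
        dh = (dlogit @ self.params["Wo"].T) * dmask

        U = self.params["U"]
        W = self.params["W"]
        for t in range(len(cache) - 1, -1, -1):
            x_t, h_prev, z, r, c, rh, m = cache[t]
            dh_eff = dh * m
            dh_prev = dh * (1.0 - m)
            dz = dh_eff * (c - h_prev)
            dc = dh_eff * z
            dh_prev += dh_eff * (1.0 - z)
            dah = dc * (1.0 - c * c)
            drh = dah @ U[:, 2 * H :].T
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            da = np.concatenate([daz, dar, dah], axis=1)
            grads["W"] += x_t.T @ da
            grads["b"] += da.sum(axis=0)
            grads["U"][:, : 2 * H] += h_prev.T @ np.concatenate([daz, dar], axis=1)
            grads["U"][:, 2 * H :] += rh.T @ dah
            dh_prev += daz @ U[:, :H].T + dar @ U[:, H : 2 * H].T
            dh = dh_prev
        return loss, grads

    # -- optimizer -----------------------------------------------------
    def adam_step(
        self,
        grads,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float = 5.0,
    ) -> None:
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        if norm > clip_norm:
            grads = {k: g * (clip_norm / norm) for k, g in grads.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            g = grads[k]
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- weights -------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()

    def weights_digest(self) -> str:
        """Stable hash of all weights (reproducibility checks)."""
        import hashlib

        md = hashlib.sha256()
        for k in sorted(self.params):
            md.update(k.encode())
            md.update(np.ascontiguousarray(self.params[k]).tobytes())
        return md.hexdigest()

    def save(self, path) -> None:
        np.savez(
            path,
            input_dim=self.input_dim,
            hidden=self.hidden,
            dropout=self.dropout,
            normalize_aux=self.normalize_aux,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "GRUClassifier":
        data = np.load(path)
        model = cls(
            int(data["input_dim"]),
            int(data["hidden"]),
            float(data["dropout"]),
            seed=0,
            normalize_aux=bool(data["normalize_aux"]),
        )
        model.set_weights({k: data[k] for k in model.params})
        return model
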
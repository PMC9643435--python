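"""Sequential container with softmax cross-entropy training."""

from __future__ import annotations

import numpy as np


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    """A stack of layers ending in logits for ``n_classes`` classes."""

    def __init__(self, layers: list, rng: np.random.Generator | None = None):
        self.layers = layers
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [
            _softmax(self.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs)

    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers if layer.trainable)

    def _trainable(self):
        return [layer for layer in self.layers if layer.trainable]

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 30,
        batch_size: int = 32,
        lr: float = 1e-3,
        optimizer: str = "adam",
        l2: float = 1e-3,
        val_fraction: float = 0.1,
        patience: int = 5,
        verbose: bool = False,
    ) -> dict:
        """Minimize cross-entropy with L2 weight penalty.

        A validation split taken from the training data drives early
        stopping (best-loss weights are restored).  ``optimizer`` is
        ``"sgd"`` (plain gradient descent) or ``"adam"``.
        """
        y = np.asarray(y, dtype=int)
        n = len(x)
        idx = self.rng.permutation(n)
        n_val = int(round(val_fraction * n)) if val_fraction > 0 else 0
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        xv, yv = x[val_idx], y[val_idx]
        xt, yt = x[tr_idx], y[tr_idx]
        n_classes = int(y.max()) + 1

        state = {}
        if optimizer == "adam":
            for layer in self._trainable():
                for pi, (p, _) in enumerate(layer.params()):
                    state[(id(layer), pi)] = (np.zeros_like(p), np.zeros_like(p), 0)
        elif optimizer != "sgd":
            raise ValueError("optimizer must be 'sgd' or 'adam'")

        best_loss, best_weights, bad_epochs = np.inf, None, 0
        history = {"train_loss": [], "val_loss": []}
        for epoch in range(epochs):
            order = self.rng.permutation(len(xt))
            losses = []
            for start in range(0, len(xt), batch_size):
                sel = order[start : start + batch_size]
                xb, yb = xt[sel], yt[sel]
                logits = self.forward(xb, train=True)
                probs = _softmax(logits)
                onehot = np.eye(n_classes)[yb]
                loss = -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1))
                losses.append(loss)
                grad = (probs - onehot) / len(xb)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                for layer in self._trainable():
                    for pi, (p, g) in enumerate(layer.params()):
                        g = g + l2 * p
                        if optimizer == "sgd":
                            p -= lr * g
                        else:
                            m, v, t = state[(id(layer), pi)]
                            t += 1
                            m = 0.9 * m + 0.1 * g
                            v = 0.999 * v + 0.001 * g * g
                            state[(id(layer), pi)] = (m, v, t)
                            mhat = m / (1 - 0.9**t)
                            vhat = v / (1 - 0.999**t)
                            p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            history["train_loss"].append(float(np.mean(losses)))
            if n_val > 0:
                pv = self.predict_proba(xv)
                val_loss = float(
                    -np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12))
                )
            else:
                val_loss = history["train_loss"][-1]
            history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} val {val_loss:.4f}")
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_weights = [
                    [p.copy() for p, _ in layer.params()] for layer in self._trainable()
                ]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
        if best_weights is not None:
            for layer, saved in zip(self._trainable(), best_weights):
                for (p, _), s in zip(layer.params(), saved):
                    p[...] = s
        return history
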
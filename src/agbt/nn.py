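"""Feed-forward networks for the downstream models (NumPy, Adam).

A shared ReLU trunk with one linear head per task.  A single head gives
the single-task DNN; several heads trained jointly with missing-label
masking give the multitask DNN.  Classification heads emit logits and
train with logistic loss; predictions are probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smiles_lm.encoder import Adam


@dataclass
class MLPConfig:
    hidden: tuple[int, ...] = (1024, 512)
    dropout: float = 0.1
    lr: float = 1e-3
    batch: int = 32
    epochs: int = 200
    patience: int = 20          # early stopping on validation loss
    val_fraction: float = 0.1   # internal split when no validation set given
    seed: int = 0


class MultiTaskMLP:
    """Shared-trunk multitask perceptron with per-task linear heads."""

    def __init__(self, n_features: int, task_types: list[str],
                 cfg: MLPConfig | None = None) -> None:
        self.cfg = cfg or MLPConfig()
        self.task_types = list(task_types)
        self.n_features = n_features
        rng = np.random.default_rng(self.cfg.seed)
        dims = [n_features, *self.cfg.hidden]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            self.params[f"w{i}"] = rng.normal(0, np.sqrt(2.0 / dims[i]),
                                              size=(dims[i], dims[i + 1]))
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self.params["head_w"] = rng.normal(0, np.sqrt(1.0 / dims[-1]),
                                           size=(dims[-1], len(task_types)))
        self.params["head_b"] = np.zeros(len(task_types))
        self._rng = rng
        self.x_mean: np.ndarray | None = None
        self.x_scale: np.ndarray | None = None
        self.y_mean = np.zeros(len(task_types))
        self.y_scale = np.ones(len(task_types))
        self.fitted = False

    # -- forward / backward ------------------------------------------------

    def _forward(self, X, train: bool):
        drop = self.cfg.dropout if train else 0.0
        h = X
        cache = []
        n_layers = len(self.cfg.hidden)
        for i in range(n_layers):
            z = h @ self.params[f"w{i}"] + self.params[f"b{i}"]
            a = np.maximum(z, 0.0)
            mask = None
            if drop > 0:
                mask = (self._rng.random(a.shape) >= drop) / (1.0 - drop)
                a = a * mask
            cache.append((h, z, mask))
            h = a
        out = h @ self.params["head_w"] + self.params["head_b"]
        return out, (cache, h)

    def _backward(self, dout, fwd_cache):
        cache, h_last = fwd_cache
        grads = {"head_w": h_last.T @ dout, "head_b": dout.sum(0)}
        dh = dout @ self.params["head_w"].T
        for i in reversed(range(len(cache))):
            h_in, z, mask = cache[i]
            if mask is not None:
                dh = dh * mask
            dz = dh * (z > 0)
            grads[f"w{i}"] = h_in.T @ dz
            grads[f"b{i}"] = dz.sum(0)
            dh = dz @ self.params[f"w{i}"].T
        return grads

    def _loss_grad(self, pred, y, mask):
        """Masked mean loss and d(loss)/d(pred)."""
        is_clf = np.array([t == "classification" for t in self.task_types])
        dpred = np.zeros_like(pred)
        n = int(mask.sum())
        loss = 0.0
        reg = mask & ~is_clf
        clf = mask & is_clf
        if reg.any():
            err = pred[reg] - y[reg]
            loss += float((err ** 2).sum())
            dpred[reg] = 2.0 * err
        if clf.any():
            z = pred[clf]
            loss += float((np.logaddexp(0.0, z) - y[clf] * z).sum())
            dpred[clf] = 1.0 / (1.0 + np.exp(-z)) - y[clf]
        return loss / n, dpred / n

    # -- training ----------------------------------------------------------

    def fit(self, X, Y, label_mask=None, X_val=None, Y_val=None,
            val_mask=None) -> "MultiTaskMLP":
        """Train with Adam and early stopping on validation loss.

        ``Y`` is (n, n_tasks); ``label_mask`` flags observed labels.  When
        no validation set is given, a seeded internal fraction is held out.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if np.isnan(X).any():
            raise ValueError("NaN in feature matrix")
        mask = np.ones(Y.shape, dtype=bool) if label_mask is None else np.asarray(label_mask)
        self.x_mean = X.mean(0)
        self.x_scale = X.std(0)
        self.x_scale[self.x_scale == 0] = 1.0
        Xn = (X - self.x_mean) / self.x_scale
        # standardize regression targets over observed labels for stable Adam steps
        Y = Y.copy()
        for j, t in enumerate(self.task_types):
            if t == "classification" or not mask[:, j].any():
                continue
            obs = Y[mask[:, j], j]
            self.y_mean[j] = obs.mean()
            self.y_scale[j] = obs.std() or 1.0
            Y[:, j] = (Y[:, j] - self.y_mean[j]) / self.y_scale[j]

        if X_val is None and self.cfg.val_fraction > 0 and len(X) >= 20:
            n_val = max(2, int(len(X) * self.cfg.val_fraction))
            order = np.random.default_rng(self.cfg.seed + 7).permutation(len(X))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            Xv, Yv, Mv = Xn[val_idx], Y[val_idx], mask[val_idx]
            Xn, Y, mask = Xn[tr_idx], Y[tr_idx], mask[tr_idx]
        elif X_val is not None:
            Xv = (np.asarray(X_val, dtype=float) - self.x_mean) / self.x_scale
            Yv = np.asarray(Y_val, dtype=float)
            if Yv.ndim == 1:
                Yv = Yv[:, None]
            Yv = (Yv - self.y_mean) / self.y_scale
            Mv = np.ones(Yv.shape, dtype=bool) if val_mask is None else np.asarray(val_mask)
        else:
            Xv = Yv = Mv = None

        opt = Adam(self.params, lr=self.cfg.lr)
        best_loss, best_params, stall = np.inf, None, 0
        n = len(Xn)
        for epoch in range(self.cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.cfg.batch):
                idx = order[start:start + self.cfg.batch]
                if not mask[idx].any():
                    continue
                pred, cache = self._forward(Xn[idx], train=True)
                _, dpred = self._loss_grad(pred, Y[idx], mask[idx])
                opt.step(self._backward(dpred, cache))
            if Xv is not None and Mv.any():
                pred, _ = self._forward(Xv, train=False)
                val_loss, _ = self._loss_grad(pred, Yv, Mv)
                if val_loss < best_loss - 1e-6:
                    best_loss, stall = val_loss, 0
                    best_params = {k: v.copy() for k, v in self.params.items()}
                else:
                    stall += 1
                    if stall >= self.cfg.patience:
                        break
        if best_params is not None:
            self.params = best_params
        self.fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        """Per-task predictions (probabilities for classification tasks)."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("NaN in feature matrix")
        Xn = (X - self.x_mean) / self.x_scale
        out, _ = self._forward(Xn, train=False)
        for j, t in enumerate(self.task_types):
            if t == "classification":
                out[:, j] = 1.0 / (1.0 + np.exp(-out[:, j]))
            else:
                out[:, j] = out[:, j] * self.y_scale[j] + self.y_mean[j]
        return out
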
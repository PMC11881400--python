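"""Two-layer baseline MLP for binary bioactivity classification.

Architecture: sparse fingerprint input -> linear (W1, b1) -> ReLU -> dropout
-> linear (W2, b2) -> sigmoid.  Trained by minibatch Adam on the BCE loss with
decoupled L2 weight decay and early stopping on validation BCE (best snapshot
restored).  Dropout uses inverted scaling (survivors divided by 1 - rate) so
deterministic inference needs no rescaling — which is also what makes MC
dropout at prediction time a drop-in.

The model is exposed statsmodels-style: ``MLPModel(data, split, config)``
with ``fit()`` returning an ``MLPResults`` that carries the trained
parameters, the training history and prediction methods.  The module-level
functions (``init_mlp``, ``train_mlp``, ``predict_logits``, ...) are thin
wrappers over the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datasets import BioactivityDataset, FoldSplit
from .metrics import bce_loss
from .utils import clip_probs, sigmoid


class TrainingError(RuntimeError):
    pass


@dataclass
class MLPConfig:
    hidden_size: int = 50
    dropout_rate: float = 0.0
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        # patience beyond the epoch budget is meaningless; clamp it
        self.patience = min(self.patience, self.max_epochs)
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")

    def replace(self, **kwargs) -> "MLPConfig":
        d = {**self.__dict__, **kwargs}
        return MLPConfig(**d)


@dataclass
class TrainedMLP:
    """Network parameters theta = (W1, b1, W2, b2) plus config and stop epoch."""

    W1: np.ndarray  # (n_features, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    config: MLPConfig
    stopped_epoch: int = 0

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[1]

    def _check_X(self, X):
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.n_features}, got {X.shape[1]}"
            )
        return X

    def hidden_features(self, X) -> np.ndarray:
        """ReLU(X W1 + b1) with dropout disabled; deterministic."""
        X = self._check_X(X)
        z1 = (X @ self.W1) + self.b1
        return np.maximum(np.asarray(z1), 0.0)

    def predict_logits(self, X, dropout_active: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits W2 . ReLU(X W1 + b1) + b2, optionally with inverted dropout."""
        h = self.hidden_features(X)
        rate = self.config.dropout_rate
        if dropout_active and rate > 0.0:
            if rng is None:
                rng = np.random.default_rng(self.config.seed)
            mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
            h = h * mask
        return h @ self.W2 + self.b2

    def predict_proba(self, X) -> np.ndarray:
        """sigmoid(logits), clipped strictly inside (0, 1)."""
        return clip_probs(sigmoid(self.predict_logits(X)))


def init_mlp(n_features: int, cfg: MLPConfig) -> TrainedMLP:
    """Fan-in-scaled uniform initialization, seeded by cfg.seed."""
    if n_features <= 0:
        raise ValueError("n_features must be > 0")
    rng = np.random.default_rng(cfg.seed)
    lim1 = 1.0 / np.sqrt(n_features)
    lim2 = 1.0 / np.sqrt(cfg.hidden_size)
    return TrainedMLP(
        W1=rng.uniform(-lim1, lim1, size=(n_features, cfg.hidden_size)),
        b1=rng.uniform(-lim1, lim1, size=cfg.hidden_size),
        W2=rng.uniform(-lim2, lim2, size=cfg.hidden_size),
        b2=float(rng.uniform(-lim2, lim2)),
        config=cfg,
    )


class _Adam:
    """Minimal Adam state over a dict of arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


@dataclass
class MLPResults:
    """Fit results: trained parameters, history, and prediction surface."""

    params: TrainedMLP
    train_bce: list = field(default_factory=list)
    valid_bce: list = field(default_factory=list)
    best_epoch: int = 0

    @property
    def stopped_epoch(self) -> int:
        return self.params.stopped_epoch

    def predict_logits(self, X, dropout_active: bool = False, rng=None):
        return self.params.predict_logits(X, dropout_active=dropout_active, rng=rng)

    def predict_proba(self, X):
        return self.params.predict_proba(X)

    def hidden_features(self, X):
        return self.params.hidden_features(X)

    def summary(self) -> str:
        c = self.params.config
        lines = [
            "MLP binary classifier (2 layers, ReLU, dropout, sigmoid)",
            f"  features: {self.params.n_features}   hidden: {self.params.hidden_size}",
            f"  dropout: {c.dropout_rate}   lr: {c.learning_rate}   weight decay: {c.weight_decay}",
            f"  epochs run: {self.stopped_epoch}   best epoch: {self.best_epoch}",
        ]
        if self.valid_bce:
            lines.append(f"  best validation BCE: {min(self.valid_bce):.6f}")
        return "\n".join(lines)


class MLPModel:
    """Model object: data + split + config; ``fit()`` returns MLPResults."""

    def __init__(self, data: BioactivityDataset, split: FoldSplit, config: MLPConfig):
        self.data = data
        self.split = split
        self.config = config

    def fit(self) -> MLPResults:
        data, split, cfg = self.data, self.split, self.config
        X_tr, y_tr, X_va, y_va, _, _ = data.split_arrays(split)
        if len(np.unique(y_tr)) < 2:
            raise TrainingError("training folds contain a single class")
        n = X_tr.shape[0]
        rng = np.random.default_rng(cfg.seed)

        net = init_mlp(X_tr.shape[1], cfg)
        params = {"W1": net.W1, "b1": net.b1, "W2": net.W2,
                  "b2": np.array([net.b2])}
        opt = _Adam(params, lr=cfg.learning_rate)
        rate, wd = cfg.dropout_rate, cfg.weight_decay
        X_tr = sp.csr_matrix(X_tr, dtype=np.float64)
        y_tr_f = y_tr.astype(np.float64)

        def current_net(epoch):
            return TrainedMLP(W1=params["W1"], b1=params["b1"], W2=params["W2"],
                              b2=float(params["b2"][0]), config=cfg,
                              stopped_epoch=epoch)

        best = {"bce": np.inf, "snapshot": None, "epoch": 0}
        res = MLPResults(params=current_net(0))
        since_improve = 0
        epoch = 0
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb = X_tr[idx]
                yb = y_tr_f[idx]
                m = len(idx)
                z1 = np.asarray(Xb @ params["W1"]) + params["b1"]
                h = np.maximum(z1, 0.0)
                if rate > 0.0:
                    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
                    hd = h * mask
                else:
                    hd = h
                logits = hd @ params["W2"] + params["b2"][0]
                delta = (sigmoid(logits) - yb) / m  # dL/dlogit for mean BCE
                gW2 = hd.T @ delta
                gb2 = np.array([delta.sum()])
                dh = np.outer(delta, params["W2"])
                if rate > 0.0:
                    dh = dh * mask
                dz1 = dh * (z1 > 0.0)
                gW1 = (Xb.T @ dz1)
                gb1 = dz1.sum(axis=0)
                opt.step(params, {"W1": np.asarray(gW1), "b1": gb1,
                                  "W2": gW2, "b2": gb2})
                if wd > 0.0:  # decoupled L2 on the weight matrices only
                    params["W1"] *= (1.0 - cfg.learning_rate * wd)
                    params["W2"] *= (1.0 - cfg.learning_rate * wd)

            net_now = current_net(epoch)
            tr_bce = bce_loss(net_now.predict_proba(X_tr), y_tr)
            va_bce = bce_loss(net_now.predict_proba(X_va), y_va)
            res.train_bce.append(tr_bce)
            res.valid_bce.append(va_bce)
            if va_bce < best["bce"]:
                best = {"bce": va_bce,
                        "snapshot": {k: v.copy() for k, v in params.items()},
                        "epoch": epoch}
                since_improve = 0
            else:
                since_improve += 1
                if since_improve > cfg.patience:
                    break

        snap = best["snapshot"] or {k: v.copy() for k, v in params.items()}
        trained = TrainedMLP(W1=snap["W1"], b1=snap["b1"], W2=snap["W2"],
                             b2=float(snap["b2"][0]), config=cfg,
                             stopped_epoch=epoch)
        res.params = trained
        res.best_epoch = best["epoch"]
        return res


def train_mlp(data: BioactivityDataset, split: FoldSplit, cfg: MLPConfig) -> TrainedMLP:
    """Train and return the best-validation-BCE parameter snapshot."""
    return MLPModel(data, split, cfg).fit().params


def predict_logits(model: TrainedMLP, X, dropout_active: bool = False, rng=None):
    return model.predict_logits(X, dropout_active=dropout_active, rng=rng)


def predict_proba(model: TrainedMLP, X):
    return model.predict_proba(X)


def hidden_features(model: TrainedMLP, X):
    return model.hidden_features(X)


def save_checkpoint(model: TrainedMLP, path) -> None:
    """Single-file archive of the four parameter arrays + config metadata."""
    np.savez(path, W1=model.W1, b1=model.b1, W2=model.W2,
             b2=np.array([model.b2]), stopped_epoch=np.array([model.stopped_epoch]),
             schema_version=np.array([1]),
             config=np.array([json.dumps(model.config.__dict__)]))


def load_checkpoint(path) -> TrainedMLP:
    with np.load(path, allow_pickle=False) as z:
        cfg = MLPConfig(**json.loads(str(z["config"][0])))
        return TrainedMLP(W1=z["W1"], b1=z["b1"], W2=z["W2"],
                          b2=float(z["b2"][0]), config=cfg,
                          stopped_epoch=int(z["stopped_epoch"][0]))
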
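"""Sampling-and-averaging uncertainty quantification: MC dropout and deep ensembles.

Both methods approximate the posterior predictive
p(y|x, D) ~= (1/M) sum_m p(y|x, theta_m) by averaging sigmoid outputs in
probability space — MC dropout over stochastic forward passes through one
trained network, deep ensembles over independently initialized retrainings.
Members of an ensemble see identical training data and split; only the
initialization (and minibatch order) seed varies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import BioactivityDataset, FoldSplit
from .mlp import MLPConfig, MLPModel, TrainedMLP
from .utils import clip_probs, sigmoid


def mc_dropout_predict(model: TrainedMLP, X, n_passes: int = 100,
                       seed: int = 0) -> np.ndarray:
    """Mean over n_passes of sigmoid(stochastic dropout logits).

    With dropout rate 0 this equals the deterministic prediction for any
    number of passes.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    if model.config.dropout_rate == 0.0:
        return model.predict_proba(X)
    rng = np.random.default_rng(seed)
    acc = np.zeros(X.shape[0], dtype=np.float64)
    for _ in range(n_passes):
        acc += sigmoid(model.predict_logits(X, dropout_active=True, rng=rng))
    return clip_probs(acc / n_passes)


@dataclass
class EnsembleModel:
    """Independently initialized base estimators sharing one architecture config."""

    members: list
    member_seeds: list

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble must be non-empty")
        if len(set(self.member_seeds)) != len(self.member_seeds):
            raise ValueError("ensemble member seeds must be distinct")

    def predict_proba(self, X) -> np.ndarray:
        return ensemble_predict(self, X)


def train_ensemble(data: BioactivityDataset, split: FoldSplit, cfg: MLPConfig,
                   n_members: int = 50, base_seed: int = 0) -> EnsembleModel:
    """Train n_members networks with seeds base_seed..base_seed+n_members-1."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    members, seeds = [], []
    for i in range(n_members):
        seed = base_seed + i
        members.append(MLPModel(data, split, cfg.replace(seed=seed)).fit().params)
        seeds.append(seed)
    return EnsembleModel(members=members, member_seeds=seeds)


def ensemble_predict(ens: EnsembleModel, X) -> np.ndarray:
    """Unweighted mean of member probabilities (probability-space averaging)."""
    if not ens.members:
        raise ValueError("ensemble must be non-empty")
    probs = np.mean([m.predict_proba(X) for m in ens.members], axis=0)
    return clip_probs(probs)


class DeepEnsemble:
    """Model-style wrapper: ``DeepEnsemble(data, split, cfg, n_members).fit()``."""

    def __init__(self, data: BioactivityDataset, split: FoldSplit, config: MLPConfig,
                 n_members: int = 50, base_seed: int = 0):
        self.data = data
        self.split = split
        self.config = config
        self.n_members = n_members
        self.base_seed = base_seed

    def fit(self) -> EnsembleModel:
        return train_ensemble(self.data, self.split, self.config,
                              n_members=self.n_members, base_seed=self.base_seed)
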
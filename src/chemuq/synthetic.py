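"""Synthetic desk-scale data with the statistical structure of assay datasets.

Two generators:

* ``gen_fingerprint_dataset`` — sparse clustered binary fingerprints with a
  logistic ground-truth activity model.  Clusters share a bit template
  (emulating chemical-series similarity), the activity probability is
  sigmoid(w.x + b) with sparse Gaussian weights, and the intercept is solved
  by bisection so the mean true probability hits a target active ratio
  (real assay extractions sit around 0.25, or 0.08 for stricter thresholds).
  Ground truth is returned so downstream parameter-recovery tests can use it.

* ``gen_miscalibrated_predictions`` — probability vectors with controlled
  over/underconfidence: latent calibrated p ~ Beta, labels ~ Bernoulli(p),
  reported probs = sigmoid(logit(p) / temperature).  temperature < 1 makes
  the reported probabilities overconfident (pushed to the extremes),
  temperature > 1 underconfident (pulled toward 0.5), temperature = 1 leaves
  them calibrated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq

from .datasets import BioactivityDataset, FingerprintMatrix, assign_folds
from .utils import sigmoid


@dataclass
class SyntheticConfig:
    """Knobs for the clustered fingerprint generator.

    Defaults are desk-scale: 2000 compounds over 1024 features in 50 clusters,
    ~40 bits per compound, active ratio 0.25, 5% label noise.
    """

    n_compounds: int = 2000
    n_features: int = 1024
    n_clusters: int = 50
    bits_per_compound: int = 40
    within_cluster_overlap: float = 0.7
    true_weight_sparsity: float = 0.05
    active_ratio_target: float = 0.25
    label_noise: float = 0.05
    logit_scale: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.active_ratio_target < 1.0):
            raise ValueError("active_ratio_target must be strictly in (0, 1)")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0.0 <= self.within_cluster_overlap <= 1.0):
            raise ValueError("within_cluster_overlap must be in [0, 1]")


def _solve_intercept(scores: np.ndarray, target: float,
                     lo: float = -40.0, hi: float = 40.0) -> float:
    """Bisection for b with mean(sigmoid(scores + b)) == target."""

    def gap(b):
        return float(np.mean(sigmoid(scores + b))) - target

    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("active ratio target infeasible within intercept bounds")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def gen_fingerprint_dataset(cfg: SyntheticConfig):
    """Generate (BioactivityDataset, true_weights, true_probs).

    ``true_weights`` has length n_features + 1; the last entry is the solved
    intercept.  Labels are Bernoulli(true_probs) with a final seeded flip at
    rate ``label_noise``.  Folds are cluster-atomic via the standard greedy
    balancer.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d, k = cfg.n_compounds, cfg.n_features, cfg.n_clusters

    cluster_id = rng.integers(0, k, size=n)
    templates = [rng.choice(d, size=cfg.bits_per_compound, replace=False)
                 for _ in range(k)]
    n_private_mean = cfg.bits_per_compound * (1.0 - cfg.within_cluster_overlap)

    rows, cols = [], []
    for i in range(n):
        tmpl = templates[cluster_id[i]]
        keep = tmpl[rng.random(tmpl.size) < cfg.within_cluster_overlap]
        n_priv = rng.poisson(n_private_mean)
        priv = rng.choice(d, size=min(n_priv, d), replace=False) if n_priv else np.empty(0, dtype=np.int64)
        bits = np.union1d(keep, priv)
        if bits.size == 0:  # clustering requires non-empty rows
            bits = tmpl[:1]
        rows.extend([i] * bits.size)
        cols.extend(bits.tolist())
    X = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, d))
    X.sum_duplicates()
    X.data = np.ones_like(X.data)

    # sparse Gaussian ground-truth weights, rescaled to a fixed logit spread
    mask = rng.random(d) < cfg.true_weight_sparsity
    w = np.where(mask, rng.normal(0.0, 1.0, size=d), 0.0)
    raw = X @ w
    sd = float(np.std(raw))
    if sd > 0:
        w *= cfg.logit_scale / sd
    scores = X @ w
    b = _solve_intercept(scores, cfg.active_ratio_target)
    true_probs = sigmoid(scores + b)

    labels = (rng.random(n) < true_probs).astype(np.int8)
    if cfg.label_noise > 0:
        flip = rng.random(n) < cfg.label_noise
        labels = np.where(flip, 1 - labels, labels).astype(np.int8)

    fold_id = assign_folds(cluster_id, n_folds=5, seed=cfg.seed)
    data = BioactivityDataset(features=FingerprintMatrix(X), labels=labels,
                              cluster_id=cluster_id.astype(np.int64),
                              fold_id=fold_id)
    true_weights = np.concatenate([w, [b]])
    return data, true_weights, true_probs


def gen_miscalibrated_predictions(n: int, temperature: float = 1.0,
                                  base_rate: float = 0.5, seed: int = 0,
                                  concentration: float = 2.0):
    """Generate (reported_probs, labels) with controlled miscalibration.

    Latent calibrated probabilities are Beta(base_rate*c, (1-base_rate)*c)
    (c = ``concentration``; dispersed so the probability bins are all
    exercised); labels are Bernoulli in those latent probabilities, and the
    reported probabilities are temperature-distorted in logit space.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if not (0.0 < base_rate < 1.0):
        raise ValueError("base_rate must be strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.beta(base_rate * concentration, (1.0 - base_rate) * concentration, size=n)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    labels = (rng.random(n) < p).astype(np.int8)
    z = np.log(p) - np.log1p(-p)
    reported = sigmoid(z / temperature)
    return reported, labels
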
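"""Shared numerical helpers: stable sigmoid/logit and probability clipping.

Probability-like model outputs are always clipped to [EPS_P, 1 - EPS_P] before
they enter a log (BCE) or a logit transform, so every downstream score stays
finite.
"""

from __future__ import annotations

import numpy as np

#: Clipping bound for probabilities; keeps BCE finite at ~16.1 nats worst case.
EPS_P: float = 1e-7


def sigmoid(z: np.ndarray | float) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def log_sigmoid(z: np.ndarray) -> np.ndarray:
    """log(sigmoid(z)) without overflow for large |z|."""
    z = np.asarray(z, dtype=np.float64)
    return -np.logaddexp(0.0, -z)


def clip_probs(p: np.ndarray, eps: float = EPS_P) -> np.ndarray:
    """Clip probabilities strictly inside (0, 1)."""
    return np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)


def logit(p: np.ndarray | float, eps: float = EPS_P) -> np.ndarray:
    """Inverse sigmoid on clipped probabilities."""
    p = clip_probs(p, eps)
    return np.log(p) - np.log1p(-p)


def check_binary_labels(y: np.ndarray) -> np.ndarray:
    """Validate and coerce a {0,1} label vector."""
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError(f"labels must be 1-D, got shape {y.shape}")
    vals = np.unique(y)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"labels must be in {{0,1}}, found values {vals}")
    return y.astype(np.int8)
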
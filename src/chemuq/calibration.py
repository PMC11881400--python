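"""Post hoc Platt scaling.

A two-parameter logistic map ``p_cal = sigmoid(a * logit + b)`` fitted by
maximum likelihood (BCE) on a held-out calibration set — here the validation
fold.  With a > 0 the map is strictly monotone, so the ranking (and thus the
AUC) of the predictions is untouched; only the probability scale changes.

Models that emit averaged probabilities rather than logits (deep ensembles,
the Bayesian last layer) are stacked through the logit transform of their
mean probability, which is the only ensemble-level "logit" available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .utils import check_binary_labels, clip_probs, log_sigmoid, logit, sigmoid


@dataclass
class PlattScaler:
    """Fitted calibration map sigmoid(slope * logit + intercept)."""

    slope: float
    intercept: float

    def transform(self, logits: np.ndarray) -> np.ndarray:
        """Apply the map; output is clipped strictly inside (0, 1)."""
        logits = np.asarray(logits, dtype=np.float64)
        return clip_probs(sigmoid(self.slope * logits + self.intercept))

    @classmethod
    def fit(cls, logits, y, smooth_targets: bool = False) -> "PlattScaler":
        return fit_platt(logits, y, smooth_targets=smooth_targets)


def fit_platt(logits, y, smooth_targets: bool = False) -> PlattScaler:
    """Maximum-likelihood fit of (slope, intercept) on calibration logits.

    The objective is the mean BCE of sigmoid(a*z + b) against the labels — a
    convex 2-parameter problem solved deterministically with BFGS from
    (a, b) = (1, 0).  ``smooth_targets`` enables Platt's classic
    (N+ + 1)/(N+ + 2) target smoothing; off by default.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = check_binary_labels(y)
    if z.ndim != 1 or z.shape[0] != y.shape[0]:
        raise ValueError("logits and y must be 1-D of equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("Platt fit requires both classes in the calibration set")

    t = y.astype(np.float64)
    if smooth_targets:
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    n = len(t)

    def nll_and_grad(params):
        a, b = params
        u = a * z + b
        # mean BCE against (possibly soft) targets t
        val = -np.mean(t * log_sigmoid(u) + (1.0 - t) * log_sigmoid(-u))
        r = (sigmoid(u) - t) / n
        return val, np.array([np.dot(r, z), np.sum(r)])

    res = minimize(nll_and_grad, x0=np.array([1.0, 0.0]), jac=True,
                   method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    a, b = float(res.x[0]), float(res.x[1])
    if a <= 0:
        warnings.warn(
            f"Platt slope {a:.4g} <= 0: the calibrated map reverses the ranking",
            UserWarning, stacklevel=2,
        )
    return PlattScaler(slope=a, intercept=b)


def apply_platt(scaler: PlattScaler, logits) -> np.ndarray:
    """Calibrated probabilities for new logits."""
    return scaler.transform(np.asarray(logits, dtype=np.float64))


def probs_to_logits(probs) -> np.ndarray:
    """log(p / (1-p)) after clipping; inverse of sigmoid on the clipped range."""
    return logit(probs)


def stack_platt(uq_probs_valid, y_valid, uq_probs_test,
                smooth_targets: bool = False) -> tuple[np.ndarray, PlattScaler]:
    """Platt-scale an averaged-probability model (MLP-E + P, HBLL + P).

    Fits on the logit transform of the validation-fold mean probabilities and
    applies the fitted map to the logit transform of the test probabilities.
    """
    scaler = fit_platt(probs_to_logits(uq_probs_valid), y_valid,
                       smooth_targets=smooth_targets)
    return scaler.transform(probs_to_logits(uq_probs_test)), scaler


class PlattCalibration:
    """Model-style wrapper: construct with calibration data, fit() -> PlattScaler."""

    def __init__(self, logits, y, smooth_targets: bool = False):
        self.logits = np.asarray(logits, dtype=np.float64)
        self.y = check_binary_labels(y)
        self.smooth_targets = smooth_targets

    def fit(self) -> PlattScaler:
        return fit_platt(self.logits, self.y, smooth_targets=self.smooth_targets)
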
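"""Evaluation scores for probabilistic binary classifiers.

Proper scores (BCE, Brier) measure calibration *and* refinement; the binned
calibration errors (ECE with fixed-width bins, ACE with equal-count bins)
measure calibration alone and are improper: a model that always predicts the
base rate has zero calibration error.  The binned calibration error is the
weighted absolute gap

    CE = (1/N) * sum_b  n_b * |acc(b) - conf(b)|

where ``conf(b)`` is the mean predicted probability in bin ``b`` and
``acc(b)`` the empirical positive fraction.  The Brier score admits the binned
Murphy decomposition  BS = REL - RES + UNC  with reliability
REL = (1/N) sum_b n_b (conf(b) - acc(b))^2, resolution
RES = (1/N) sum_b n_b (acc(b) - ybar)^2 and uncertainty UNC = ybar(1 - ybar);
the identity is exact whenever predictions are constant within bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .utils import check_binary_labels, clip_probs


class MetricUndefinedError(ValueError):
    """A metric is undefined for the given input (e.g. AUC with one class)."""


class DegenerateTestError(ValueError):
    """A statistical test is degenerate (e.g. zero-variance paired differences)."""


def _validate(probs, y):
    probs = np.asarray(probs, dtype=np.float64)
    y = check_binary_labels(y)
    if probs.ndim != 1 or probs.shape[0] != y.shape[0]:
        raise ValueError("probs and y must be 1-D vectors of equal length")
    if probs.shape[0] == 0:
        raise ValueError("empty input")
    return probs, y


def brier_score(probs, y) -> float:
    """Mean squared error between predicted probabilities and labels."""
    probs, y = _validate(probs, y)
    return float(np.mean((probs - y) ** 2))


def bce_loss(probs, y) -> float:
    """Binary cross-entropy in natural log; probabilities are clipped first."""
    probs, y = _validate(probs, y)
    p = clip_probs(probs)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def accuracy(probs, y, threshold: float = 0.5) -> float:
    """Fraction of predictions on the correct side of ``threshold``."""
    probs, y = _validate(probs, y)
    return float(np.mean((probs >= threshold).astype(np.int8) == y))


def auc(probs, y) -> float:
    """Area under the ROC curve (Mann-Whitney statistic; ties count 1/2)."""
    probs, y = _validate(probs, y)
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("AUC undefined: only one class present")
    return float(roc_auc_score(y, probs))


@dataclass
class BinStats:
    """Per-bin counts, mean confidence and empirical accuracy.

    Empty bins carry ``counts == 0`` and zero conf/acc; they contribute
    nothing to the weighted calibration error.
    """

    counts: np.ndarray
    conf: np.ndarray
    acc: np.ndarray
    edges: np.ndarray | None = None
    scheme: str = "fixed_width"

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Tidy reliability-diagram table (one row per bin)."""
        df = pd.DataFrame(
            {"bin": np.arange(self.n_bins), "n": self.counts,
             "conf": self.conf, "acc": self.acc}
        )
        if self.edges is not None:
            df["lower"] = self.edges[:-1]
            df["upper"] = self.edges[1:]
        df["scheme"] = self.scheme
        return df


def _bin_membership(probs: np.ndarray, n_bins: int, scheme: str) -> np.ndarray:
    """Bin index per prediction.

    fixed_width: half-open edges [k/B, (k+1)/B), last bin closed so 1.0 falls
    into bin B-1.  equal_count: stable sort, cut into B contiguous rank groups
    whose sizes differ by at most one (earlier groups take the extra item);
    tied prediction values are then coalesced into the bin of their first
    sorted occurrence, so identical predictions never straddle a bin edge —
    without this a constant base-rate predictor would show spurious
    calibration error under the adaptive scheme.
    """
    n = probs.shape[0]
    if scheme == "fixed_width":
        idx = np.floor(probs * n_bins).astype(np.int64)
        return np.minimum(idx, n_bins - 1)
    if scheme == "equal_count":
        order = np.argsort(probs, kind="stable")
        idx = np.empty(n, dtype=np.int64)
        for b, grp in enumerate(np.array_split(order, n_bins)):
            idx[grp] = b
        sorted_p = probs[order]
        bin_sorted = idx[order]
        run_start = np.flatnonzero(
            np.concatenate([[True], np.diff(sorted_p) != 0]))
        for s, e in zip(run_start, np.append(run_start[1:], n)):
            bin_sorted[s:e] = bin_sorted[s]
        idx[order] = bin_sorted
        return idx
    raise ValueError(f"unknown binning scheme {scheme!r}")


def bin_stats(probs, y, n_bins: int = 10, scheme: str = "fixed_width") -> BinStats:
    """Compute per-bin statistics under either binning scheme."""
    probs, y = _validate(probs, y)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    idx = _bin_membership(probs, n_bins, scheme)
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    psum = np.bincount(idx, weights=probs, minlength=n_bins)
    ysum = np.bincount(idx, weights=y.astype(np.float64), minlength=n_bins)
    nz = counts > 0
    conf = np.zeros(n_bins)
    acc = np.zeros(n_bins)
    conf[nz] = psum[nz] / counts[nz]
    acc[nz] = ysum[nz] / counts[nz]
    edges = None
    if scheme == "fixed_width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    return BinStats(counts=counts, conf=conf, acc=acc, edges=edges, scheme=scheme)


def binned_ce(probs, y, n_bins: int = 10,
              scheme: str = "fixed_width") -> tuple[float, BinStats]:
    """Weighted binned calibration error (ECE for fixed_width, ACE for equal_count)."""
    bs = bin_stats(probs, y, n_bins=n_bins, scheme=scheme)
    n = int(bs.counts.sum())
    ce = float(np.sum(bs.counts * np.abs(bs.acc - bs.conf)) / n)
    return ce, bs


def expected_calibration_error(probs, y, n_bins: int = 10) -> float:
    return binned_ce(probs, y, n_bins=n_bins, scheme="fixed_width")[0]


def adaptive_calibration_error(probs, y, n_bins: int = 10) -> float:
    return binned_ce(probs, y, n_bins=n_bins, scheme="equal_count")[0]


def brier_decomposition(probs, y, n_bins: int = 10,
                        scheme: str = "fixed_width") -> tuple[float, float, float]:
    """Binned Murphy decomposition of the Brier score.

    Returns (reliability, resolution, uncertainty); ybar is the empirical base
    rate of the evaluated set.  REL - RES + UNC equals BS exactly when
    predictions are constant within each bin.
    """
    probs, y = _validate(probs, y)
    bs = bin_stats(probs, y, n_bins=n_bins, scheme=scheme)
    n = int(bs.counts.sum())
    ybar = float(np.mean(y))
    rel = float(np.sum(bs.counts * (bs.conf - bs.acc) ** 2) / n)
    res = float(np.sum(bs.counts * (bs.acc - ybar) ** 2) / n)
    unc = ybar * (1.0 - ybar)
    return rel, res, unc


def compare_models(metric_repeats_a, metric_repeats_b,
                   paired: bool = True) -> tuple[float, float]:
    """Two-sided t-test between per-repeat metric vectors.

    Paired repeats (same base-model seeds) use Student's paired t; otherwise a
    Welch unpaired t is used.
    """
    a = np.asarray(metric_repeats_a, dtype=np.float64)
    b = np.asarray(metric_repeats_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two repeats per model")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            raise DegenerateTestError(
                "paired differences have zero variance; t-test undefined"
            )
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CalibrationReport:
    """Metric bundle for one model's test predictions."""

    bce: float
    brier: float
    ece: float
    ace: float
    auc: float
    accuracy: float
    reliability: float
    resolution: float
    uncertainty: float
    n_test: int
    n_bins: int = 10
    ece_bins: BinStats | None = field(default=None, repr=False)
    ace_bins: BinStats | None = field(default=None, repr=False)

    @classmethod
    def from_predictions(cls, probs, y, n_bins: int = 10) -> "CalibrationReport":
        """Score predictions with a shared binning config.

        A single-class evaluation set leaves AUC as NaN; all other metrics are
        still computed.
        """
        probs, y = _validate(probs, y)
        ece, ece_bins = binned_ce(probs, y, n_bins=n_bins, scheme="fixed_width")
        ace, ace_bins = binned_ce(probs, y, n_bins=n_bins, scheme="equal_count")
        rel, res, unc = brier_decomposition(probs, y, n_bins=n_bins)
        try:
            auc_val = auc(probs, y)
        except MetricUndefinedError:
            auc_val = float("nan")
        return cls(
            bce=bce_loss(probs, y), brier=brier_score(probs, y),
            ece=ece, ace=ace, auc=auc_val, accuracy=accuracy(probs, y),
            reliability=rel, resolution=res, uncertainty=unc,
            n_test=len(y), n_bins=n_bins, ece_bins=ece_bins, ace_bins=ace_bins,
        )

    def to_dict(self) -> dict:
        return {
            "bce": self.bce, "brier": self.brier, "ece": self.ece,
            "ace": self.ace, "auc": self.auc, "accuracy": self.accuracy,
            "reliability": self.reliability, "resolution": self.resolution,
            "uncertainty": self.uncertainty, "n_test": self.n_test,
            "n_bins": self.n_bins,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def bins_frame(self) -> pd.DataFrame:
        """Reliability-diagram data for both binning schemes, tidy format."""
        frames = []
        if self.ece_bins is not None:
            frames.append(self.ece_bins.to_frame())
        if self.ace_bins is not None:
            frames.append(self.ace_bins.to_frame())
        return pd.concat(frames, ignore_index=True)


def evaluate_model(probs, y_test, n_bins: int = 10) -> CalibrationReport:
    """Score a model's test predictions (alias for CalibrationReport.from_predictions)."""
    return CalibrationReport.from_predictions(probs, y_test, n_bins=n_bins)
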
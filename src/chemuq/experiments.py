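"""Replicated desk-scale experiments.

Two compact, fully seeded experiments that exercise the package end to end
on synthetic data:

* :func:`selection_metric_experiment` — does calibration-aware model
  selection (validation BCE) pick models with test calibration at least as
  good as accuracy-driven selection?  An over-capacity unregularized
  network competes against a strongly regularized one; each replicate draws
  a fresh clustered dataset, selects a config under each HP metric
  (repeat-averaged validation score) and compares the selected configs'
  repeat-averaged test ECE.

* :func:`stacking_experiment` — does Platt-stacking help or hurt?
  (a) an overconfident averaged-probability model (temperature-distorted
  predictions standing in for an overconfident ensemble) must strictly
  improve; (b) an HMC Bayesian last layer fitted on synthetic data, already
  calibrated by construction of its prior tuning, must change by less than
  the binning noise of the ECE estimate.

The dataset sizes here are chosen so each experiment runs in minutes on one
CPU while leaving the qualitative comparisons well resolved; they are
documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .calibration import stack_platt
from .datasets import make_split
from .hbll import HMCConfig, fit_hbll, hbll_predict, tune_prior_precision
from .metrics import expected_calibration_error
from .mlp import MLPConfig, MLPModel
from .selection import select_from_configs
from .synthetic import (SyntheticConfig, gen_fingerprint_dataset,
                        gen_miscalibrated_predictions)

#: candidate configs for the selection experiment: over-capacity vs regularized
OVER_CAPACITY = MLPConfig(hidden_size=1024, dropout_rate=0.0, weight_decay=0.0,
                          learning_rate=3e-3, max_epochs=30, patience=30)
REGULARIZED = MLPConfig(hidden_size=32, dropout_rate=0.7, weight_decay=1e-3,
                        learning_rate=3e-3, max_epochs=30, patience=30)


def _selection_dataset(seed: int) -> SyntheticConfig:
    # strong-signal clustered data: enough clusters that folds are comparable,
    # 10% label noise so overconfidence is punished on held-out folds
    return SyntheticConfig(n_compounds=1200, n_features=256, n_clusters=60,
                           label_noise=0.1, logit_scale=4.0, seed=seed)


def selection_metric_experiment(n_replicates: int = 10, seed: int = 0,
                                n_repeats: int = 3, n_bins: int = 10) -> dict:
    """Compare BCE-driven vs ACC-driven model selection over replicates.

    Returns a dict with per-replicate test ECEs of the BCE- and ACC-selected
    configs and the fraction of replicates in which the BCE-selected config's
    test ECE is no worse.
    """
    split = make_split(3, 4)
    candidates = [OVER_CAPACITY, REGULARIZED]
    ece_bce, ece_acc = [], []
    for rep in range(n_replicates):
        data, _, _ = gen_fingerprint_dataset(_selection_dataset(seed + 1000 + rep))
        te = data.fold_indices(split.test_fold)
        X_te, y_te = data.features.data[te], data.labels[te]
        sel = select_from_configs(data, split, candidates,
                                  hp_metrics=("bce", "acc"),
                                  n_repeats=n_repeats, base_seed=seed,
                                  n_bins=n_bins)
        test_ece = {}
        for cfg in candidates:
            key = (cfg.hidden_size, cfg.dropout_rate)
            eces = [expected_calibration_error(
                MLPModel(data, split, cfg.replace(seed=seed + r)).fit()
                .predict_proba(X_te), y_te, n_bins=n_bins)
                for r in range(n_repeats)]
            test_ece[key] = float(np.mean(eces))
        pick = {m: (sel[m].best_config.hidden_size,
                    sel[m].best_config.dropout_rate) for m in ("bce", "acc")}
        ece_bce.append(test_ece[pick["bce"]])
        ece_acc.append(test_ece[pick["acc"]])
    wins = sum(b <= a + 1e-12 for b, a in zip(ece_bce, ece_acc))
    return {"ece_bce_selected": ece_bce, "ece_acc_selected": ece_acc,
            "wins": int(wins), "n_replicates": n_replicates,
            "win_rate": wins / n_replicates}


def stacking_experiment(seed: int = 0, n_bins: int = 10,
                        n_overconfident: int = 50_000) -> dict:
    """Platt-stacking on an overconfident averager and on a calibrated HBLL.

    Returns test-set ECEs before/after stacking for both cases, plus the
    binning-noise bound  0.4 * sqrt(B / n_test)  (the expected ECE of an
    exactly calibrated predictor with B bins and n_test points).
    """
    # (a) overconfident averaged-probability model (temperature 0.5)
    pv, yv = gen_miscalibrated_predictions(n_overconfident, temperature=0.5,
                                           seed=seed)
    pt, yt = gen_miscalibrated_predictions(n_overconfident, temperature=0.5,
                                           seed=seed + 1)
    cal, _ = stack_platt(pv, yv, pt)
    over_before = expected_calibration_error(pt, yt, n_bins=n_bins)
    over_after = expected_calibration_error(cal, yt, n_bins=n_bins)

    # (b) HBLL on clustered synthetic data, prior tuned on the validation fold
    data, _, _ = gen_fingerprint_dataset(SyntheticConfig(
        n_compounds=3000, n_features=256, n_clusters=80, label_noise=0.1,
        logit_scale=3.0, seed=seed + 7))
    split = make_split(3, 4)
    va, te = data.fold_indices(3), data.fold_indices(4)
    X_va, y_va = data.features.data[va], data.labels[va]
    X_te, y_te = data.features.data[te], data.labels[te]
    res = MLPModel(data, split, MLPConfig(hidden_size=32, dropout_rate=0.2,
                                          max_epochs=30, seed=seed)).fit()
    hmc = HMCConfig(n_burnin=100, n_samples=500, leapfrog_steps=25,
                    step_size=0.2, seed=seed)
    tau, _ = tune_prior_precision(res.params, data, split,
                                  tau_grid=[0.1, 1.0, 10.0, 100.0], cfg=hmc)
    samples = fit_hbll(res.params, data, split, tau, hmc)
    hb_va = hbll_predict(samples, res.params, X_va)
    hb_te = hbll_predict(samples, res.params, X_te)
    hb_cal, _ = stack_platt(hb_va, y_va, hb_te)
    hbll_before = expected_calibration_error(hb_te, y_te, n_bins=n_bins)
    hbll_after = expected_calibration_error(hb_cal, y_te, n_bins=n_bins)
    noise_bound = 0.4 * np.sqrt(n_bins / len(y_te))

    return {"overconfident_ece_before": float(over_before),
            "overconfident_ece_after": float(over_after),
            "hbll_ece_before": float(hbll_before),
            "hbll_ece_after": float(hbll_after),
            "hbll_tau": float(tau),
            "binning_noise_bound": float(noise_bound),
            "n_test_hbll": int(len(y_te)),
            "n_overconfident": int(n_overconfident)}
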
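"""Calibration-aware model selection and the study engine.

Grid search over MLP hyperparameters driven by one of four validation
metrics — ACC, AUC (maximized) or BCE, ACE (minimized) — averaged over
seeded repeats; then test-fold evaluation of the selected model and of the
uncertainty/calibration variants built on top of it:

  mlp      baseline network
  mlp_p    baseline + Platt scaling fitted on the validation fold
  mlp_d    MC dropout at inference (shares the baseline HP config)
  mlp_e    deep ensemble of independently initialized members
  hbll     HMC Bayesian last layer (prior precision tuned on validation)
  mlp_e_p  ensemble, Platt-stacked through the logit of its mean probability
  hbll_p   HBLL, Platt-stacked the same way

Per-repeat metric vectors are compared with two-sided t-tests at p = 0.05:
paired among the baseline and its modifications (mlp, mlp_p, mlp_d, hbll,
hbll_p — they share base-model seeds), Welch-unpaired otherwise.  Ensembles
default to 5 repeats, everything else to 10.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import fit_platt, stack_platt
from .datasets import BioactivityDataset, FoldSplit
from .ensembles import mc_dropout_predict, train_ensemble
from .hbll import DEFAULT_TAU_GRID, HMCConfig, fit_hbll, hbll_predict, tune_prior_precision
from .metrics import (CalibrationReport, DegenerateTestError, accuracy,
                      adaptive_calibration_error, auc, bce_loss, compare_models)
from .mlp import MLPConfig, MLPModel, TrainingError

logger = logging.getLogger(__name__)

#: methods compared with paired t-tests (baseline and its modifications)
PAIRED_FAMILY = frozenset({"mlp", "mlp_p", "mlp_d", "hbll", "hbll_p"})
ALL_METHODS = ("mlp", "mlp_p", "mlp_d", "mlp_e", "hbll", "mlp_e_p", "hbll_p")
#: metric -> direction used to flag the best model
METRIC_DIRECTIONS = {"bce": min, "brier": min, "ece": min, "ace": min,
                     "auc": max, "accuracy": max}
HP_METRIC_DIRECTIONS = {"acc": max, "auc": max, "bce": min, "ace": min}


@dataclass
class HPGrid:
    """Hyperparameter grid (Cartesian product, lexicographic order)."""

    hidden_sizes: tuple = (50, 200, 1000)
    dropout_rates: tuple = (0.0, 0.2, 0.4, 0.6)
    learning_rates: tuple = (1e-3, 1e-4)
    weight_decays: tuple = (0.0, 1e-5, 1e-4)

    def configs(self, base: MLPConfig) -> list[MLPConfig]:
        combos = itertools.product(self.hidden_sizes, self.dropout_rates,
                                   self.learning_rates, self.weight_decays)
        out = [base.replace(hidden_size=h, dropout_rate=dr,
                            learning_rate=lr, weight_decay=wd)
               for h, dr, lr, wd in combos]
        if not out:
            raise ValueError("hyperparameter grid is empty")
        return out


@dataclass
class SelectionResult:
    best_config: MLPConfig
    hp_metric: str
    per_config_table: pd.DataFrame
    n_repeats: int


def _validation_metric(probs, y, hp_metric: str, n_bins: int) -> float:
    if hp_metric == "bce":
        return bce_loss(probs, y)
    if hp_metric == "ace":
        return adaptive_calibration_error(probs, y, n_bins=n_bins)
    if hp_metric == "auc":
        return auc(probs, y)
    if hp_metric == "acc":
        return accuracy(probs, y)
    raise ValueError(f"unknown hp_metric {hp_metric!r}")


def grid_search(data: BioactivityDataset, split: FoldSplit, grid: HPGrid,
                hp_metric: str = "bce", n_repeats: int = 10, base_seed: int = 0,
                base_config: MLPConfig | None = None,
                n_bins: int = 10) -> SelectionResult:
    """Exhaustive search; each config scored by its mean validation metric.

    Repeats use seeds base_seed..base_seed+n_repeats-1.  A config whose
    training fails is logged and skipped; ties keep the first config in
    lexicographic grid order.
    """
    if hp_metric not in HP_METRIC_DIRECTIONS:
        raise ValueError(f"hp_metric must be one of {sorted(HP_METRIC_DIRECTIONS)}")
    base = base_config or MLPConfig()
    va = data.fold_indices(split.valid_fold)
    X_va, y_va = data.features.data[va], data.labels[va]
    better_is_max = HP_METRIC_DIRECTIONS[hp_metric] is max

    rows = []
    best = None
    for config in grid.configs(base):
        vals = []
        try:
            for r in range(n_repeats):
                res = MLPModel(data, split, config.replace(seed=base_seed + r)).fit()
                vals.append(_validation_metric(res.predict_proba(X_va), y_va,
                                               hp_metric, n_bins))
        except TrainingError as exc:
            logger.warning("config %s failed: %s", config, exc)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"hidden_size": config.hidden_size,
                     "dropout_rate": config.dropout_rate,
                     "learning_rate": config.learning_rate,
                     "weight_decay": config.weight_decay,
                     "mean_valid_metric": mean, "sd_valid_metric": sd})
        if best is None or (mean > best[0] if better_is_max else mean < best[0]):
            best = (mean, config)
    if best is None:
        raise TrainingError("every configuration in the grid failed to train")
    return SelectionResult(best_config=best[1], hp_metric=hp_metric,
                           per_config_table=pd.DataFrame(rows),
                           n_repeats=n_repeats)


def grid_search_multi(data: BioactivityDataset, split: FoldSplit, grid: HPGrid,
                      hp_metrics=("acc", "auc", "bce", "ace"),
                      n_repeats: int = 10, base_seed: int = 0,
                      base_config: MLPConfig | None = None,
                      n_bins: int = 10) -> dict[str, SelectionResult]:
    """One training pass per config x repeat, scored under every HP metric.

    Equivalent to calling :func:`grid_search` once per metric but without
    retraining; returns {metric: SelectionResult}.
    """
    base = base_config or MLPConfig()
    return select_from_configs(data, split, grid.configs(base),
                               hp_metrics=hp_metrics, n_repeats=n_repeats,
                               base_seed=base_seed, n_bins=n_bins)


def select_from_configs(data: BioactivityDataset, split: FoldSplit, configs,
                        hp_metrics=("acc", "auc", "bce", "ace"),
                        n_repeats: int = 10, base_seed: int = 0,
                        n_bins: int = 10) -> dict[str, SelectionResult]:
    """Model selection over an explicit candidate-config list.

    Each candidate is trained n_repeats times; its validation predictions are
    scored under every requested HP metric.  Ties keep the earlier candidate.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("candidate config list is empty")
    for m in hp_metrics:
        if m not in HP_METRIC_DIRECTIONS:
            raise ValueError(f"hp_metric must be one of {sorted(HP_METRIC_DIRECTIONS)}")
    va = data.fold_indices(split.valid_fold)
    X_va, y_va = data.features.data[va], data.labels[va]

    rows = {m: [] for m in hp_metrics}
    best = {m: None for m in hp_metrics}
    for config in configs:
        vals = {m: [] for m in hp_metrics}
        try:
            for r in range(n_repeats):
                res = MLPModel(data, split, config.replace(seed=base_seed + r)).fit()
                probs = res.predict_proba(X_va)
                for m in hp_metrics:
                    vals[m].append(_validation_metric(probs, y_va, m, n_bins))
        except TrainingError as exc:
            logger.warning("config %s failed: %s", config, exc)
            continue
        for m in hp_metrics:
            mean = float(np.mean(vals[m]))
            sd = float(np.std(vals[m], ddof=1)) if len(vals[m]) > 1 else 0.0
            rows[m].append({"hidden_size": config.hidden_size,
                            "dropout_rate": config.dropout_rate,
                            "learning_rate": config.learning_rate,
                            "weight_decay": config.weight_decay,
                            "mean_valid_metric": mean, "sd_valid_metric": sd})
            better_is_max = HP_METRIC_DIRECTIONS[m] is max
            if best[m] is None or (mean > best[m][0] if better_is_max
                                   else mean < best[m][0]):
                best[m] = (mean, config)
    if any(b is None for b in best.values()):
        raise TrainingError("every configuration in the grid failed to train")
    return {m: SelectionResult(best_config=best[m][1], hp_metric=m,
                               per_config_table=pd.DataFrame(rows[m]),
                               n_repeats=n_repeats)
            for m in hp_metrics}


@dataclass
class StudyResult:
    """Per-repeat reports, aggregates and pairwise significance tests."""

    per_repeat: pd.DataFrame
    selection: SelectionResult | None
    hbll_tau: float | None
    seeds: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        metrics = list(METRIC_DIRECTIONS)
        g = self.per_repeat.groupby("method")[metrics]
        agg = g.agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        agg["n_repeats"] = self.per_repeat.groupby("method").size()
        return agg.reset_index()

    def metric_vectors(self, metric: str) -> dict[str, np.ndarray]:
        out = {}
        for method, grp in self.per_repeat.groupby("method"):
            out[method] = grp.sort_values("repeat")[metric].to_numpy()
        return out

    def ttest_table(self, metric: str) -> pd.DataFrame:
        """All pairwise two-sided t-tests for one metric."""
        vecs = self.metric_vectors(metric)
        rows = []
        for a, b in itertools.combinations(sorted(vecs), 2):
            paired = a in PAIRED_FAMILY and b in PAIRED_FAMILY
            try:
                t, p = compare_models(vecs[a], vecs[b], paired=paired)
            except DegenerateTestError:
                t, p = float("nan"), float("nan")
            rows.append({"metric": metric, "model_a": a, "model_b": b,
                         "paired": paired, "t_statistic": t, "p_value": p})
        return pd.DataFrame(rows)

    def best_models(self, metric: str, alpha: float = 0.05):
        """Best method for a metric plus all statistically indistinguishable ones."""
        vecs = self.metric_vectors(metric)
        direction = METRIC_DIRECTIONS[metric]
        means = {m: float(np.mean(v)) for m, v in vecs.items()}
        best = direction(means, key=means.get)
        flagged = {best}
        for m in vecs:
            if m == best:
                continue
            paired = m in PAIRED_FAMILY and best in PAIRED_FAMILY
            try:
                _, p = compare_models(vecs[m], vecs[best], paired=paired)
            except DegenerateTestError:
                p = 1.0
            if p >= alpha:
                flagged.add(m)
        return best, flagged


def run_study(data: BioactivityDataset, split: FoldSplit,
              grid: HPGrid | None = None,
              methods=("mlp", "mlp_p", "mlp_e", "hbll"),
              hp_metric: str = "bce", n_repeats: int = 10,
              n_ensemble_repeats: int = 5, n_members: int = 50,
              n_dropout_passes: int = 100,
              tau_grid=DEFAULT_TAU_GRID, hmc_config: HMCConfig | None = None,
              base_seed: int = 0, n_bins: int = 10,
              base_config: MLPConfig | None = None,
              selection_repeats: int | None = None) -> StudyResult:
    """Run the model-selection + model-calibration study on one split.

    When a grid is given, hyperparameters are first selected on the
    validation fold; otherwise ``base_config`` is used as-is.  Baseline
    repeats share seeds with their modifications so paired t-tests apply;
    ensembles get their own seed block and repeat count.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("methods must be non-empty")
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    selection = None
    if grid is not None:
        selection = grid_search(data, split, grid, hp_metric=hp_metric,
                                n_repeats=selection_repeats or n_repeats,
                                base_seed=base_seed, base_config=base_config,
                                n_bins=n_bins)
        config = selection.best_config
    else:
        config = base_config or MLPConfig()

    hmc_config = hmc_config or HMCConfig()
    _, _, X_va, y_va, X_te, y_te = data.split_arrays(split)
    repeat_seed0 = base_seed + 100
    ens_seed0 = base_seed + 10_000

    needs_base = [m for m in methods if m in PAIRED_FAMILY]
    needs_hbll = [m for m in methods if m in ("hbll", "hbll_p")]

    hbll_tau = None
    rows = []

    base_results = {}
    if needs_base:
        for r in range(n_repeats):
            seed = repeat_seed0 + r
            base_results[r] = MLPModel(data, split, config.replace(seed=seed)).fit()

    if needs_hbll:
        # prior precision tuned once on the first repeat's network
        hbll_tau, _ = tune_prior_precision(base_results[0].params, data, split,
                                           tau_grid=tau_grid, cfg=hmc_config,
                                           criterion="bce")

    def add_row(method, repeat, seed, probs):
        rep = CalibrationReport.from_predictions(probs, y_te, n_bins=n_bins)
        rows.append({"method": method, "repeat": repeat, "seed": seed,
                     **rep.to_dict()})

    for r, res in base_results.items():
        seed = repeat_seed0 + r
        probs_test = res.predict_proba(X_te)
        if "mlp" in methods:
            add_row("mlp", r, seed, probs_test)
        if "mlp_p" in methods:
            scaler = fit_platt(res.predict_logits(X_va), y_va)
            add_row("mlp_p", r, seed, scaler.transform(res.predict_logits(X_te)))
        if "mlp_d" in methods:
            add_row("mlp_d", r, seed,
                    mc_dropout_predict(res.params, X_te,
                                       n_passes=n_dropout_passes, seed=seed))
        if needs_hbll:
            samples = fit_hbll(res.params, data, split, hbll_tau,
                               hmc_config.replace(seed=seed))
            hb_test = hbll_predict(samples, res.params, X_te)
            if "hbll" in methods:
                add_row("hbll", r, seed, hb_test)
            if "hbll_p" in methods:
                hb_va = hbll_predict(samples, res.params, X_va)
                cal, _ = stack_platt(hb_va, y_va, hb_test)
                add_row("hbll_p", r, seed, cal)

    if "mlp_e" in methods or "mlp_e_p" in methods:
        for e in range(n_ensemble_repeats):
            seed = ens_seed0 + e * n_members
            ens = train_ensemble(data, split, config, n_members=n_members,
                                 base_seed=seed)
            probs_test = ens.predict_proba(X_te)
            if "mlp_e" in methods:
                add_row("mlp_e", e, seed, probs_test)
            if "mlp_e_p" in methods:
                cal, _ = stack_platt(ens.predict_proba(X_va), y_va, probs_test)
                add_row("mlp_e_p", e, seed, cal)

    per_repeat = pd.DataFrame(rows)
    seeds = {"base_seed": base_seed, "repeat_seeds": [repeat_seed0 + r for r in range(n_repeats)],
             "ensemble_seeds": [ens_seed0 + e * n_members for e in range(n_ensemble_repeats)],
             "config": config.__dict__, "hbll_tau": hbll_tau,
             "n_members": n_members, "n_dropout_passes": n_dropout_passes}
    return StudyResult(per_repeat=per_repeat, selection=selection,
                       hbll_tau=hbll_tau, seeds=seeds)
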
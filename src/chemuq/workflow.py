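"""Configuration-driven experiment runner and report export.

An :class:`ExperimentConfig` (YAML round-trippable) names the data source
(compound table, MTX matrix, or the synthetic generator), the split, the
hyperparameter grid, the methods to compare, and the metric/HMC settings.
``run_experiment`` executes the study and ``write_report`` emits the CSV/JSON
surfaces: per-repeat metrics, aggregate mean±sd, the t-test matrix and a
machine-readable run manifest for exact replay.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datasets import (BioactivityDataset, load_compound_table,
                       load_feature_matrix, make_split)
from .hbll import DEFAULT_TAU_GRID, HMCConfig
from .mlp import MLPConfig
from .selection import HPGrid, METRIC_DIRECTIONS, StudyResult, run_study
from .synthetic import SyntheticConfig, gen_fingerprint_dataset

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class ExperimentConfig:
    """Everything needed to replay one experiment."""

    source: str = "synthetic"  # synthetic | table | mtx
    table_path: str | None = None
    smiles_column: str = "smiles"
    label_column: str = "label"
    pic50_threshold: float | None = None
    mtx_path: str | None = None
    labels_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    cluster_threshold: float = 0.6
    valid_fold: int = 3
    test_fold: int = 4
    seed: int = 0
    grid: dict | None = None
    base_config: dict = field(default_factory=dict)
    hp_metric: str = "bce"
    methods: tuple = ("mlp", "mlp_p", "mlp_e", "hbll")
    n_repeats: int = 10
    n_ensemble_repeats: int = 5
    n_members: int = 50
    n_dropout_passes: int = 100
    tau_grid: tuple = tuple(DEFAULT_TAU_GRID)
    hmc: dict = field(default_factory=dict)
    n_bins: int = 10
    output_dir: str = "chemuq_run"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["methods"] = list(d["methods"])
        d["tau_grid"] = [float(t) for t in d["tau_grid"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "tau_grid" in d:
            d["tau_grid"] = tuple(d["tau_grid"])
        return cls(**d)


def load_dataset(cfg: ExperimentConfig) -> BioactivityDataset:
    """Materialize the dataset named by the config."""
    if cfg.source == "synthetic":
        syn = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
        data, _, _ = gen_fingerprint_dataset(syn)
        return data
    if cfg.source == "table":
        if not cfg.table_path:
            raise ValueError("table source requires table_path")
        return load_compound_table(cfg.table_path, smiles_column=cfg.smiles_column,
                                   label_column=cfg.label_column,
                                   pic50_threshold=cfg.pic50_threshold,
                                   cluster_threshold=cfg.cluster_threshold,
                                   order_seed=cfg.seed, fold_seed=cfg.seed)
    if cfg.source == "mtx":
        if not (cfg.mtx_path and cfg.labels_path):
            raise ValueError("mtx source requires mtx_path and labels_path")
        return load_feature_matrix(cfg.mtx_path, cfg.labels_path,
                                   cluster_threshold=cfg.cluster_threshold,
                                   order_seed=cfg.seed, fold_seed=cfg.seed)
    raise ValueError(f"unknown source {cfg.source!r}")


def run_experiment(cfg: ExperimentConfig) -> StudyResult:
    data = load_dataset(cfg)
    split = make_split(cfg.valid_fold, cfg.test_fold)
    grid = HPGrid(**cfg.grid) if cfg.grid else None
    base = MLPConfig(**{"seed": cfg.seed, **cfg.base_config})
    hmc = HMCConfig(**{"seed": cfg.seed, **cfg.hmc})
    return run_study(data, split, grid=grid, methods=cfg.methods,
                     hp_metric=cfg.hp_metric, n_repeats=cfg.n_repeats,
                     n_ensemble_repeats=cfg.n_ensemble_repeats,
                     n_members=cfg.n_members,
                     n_dropout_passes=cfg.n_dropout_passes,
                     tau_grid=cfg.tau_grid, hmc_config=hmc,
                     base_seed=cfg.seed, n_bins=cfg.n_bins, base_config=base)


def write_report(study: StudyResult, outdir, config: ExperimentConfig | None = None,
                 elapsed: float | None = None) -> dict:
    """Write per-repeat, aggregate and t-test CSVs plus a JSON manifest.

    Returns a dict of output paths.  Fails before creating anything if the
    study has no rows.
    """
    if study.per_repeat.empty:
        raise ValueError("study results are empty; nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    per_repeat = outdir / "per_repeat.csv"
    study.per_repeat.to_csv(per_repeat, index=False, float_format=_FLOAT_FMT)
    paths["per_repeat"] = per_repeat

    agg = outdir / "aggregate.csv"
    study.aggregate().to_csv(agg, index=False, float_format=_FLOAT_FMT)
    paths["aggregate"] = agg

    import pandas as pd

    tt = pd.concat([study.ttest_table(m) for m in METRIC_DIRECTIONS],
                   ignore_index=True)
    ttests = outdir / "ttests.csv"
    tt.to_csv(ttests, index=False, float_format=_FLOAT_FMT)
    paths["ttests"] = ttests

    if study.selection is not None:
        sel = outdir / "grid_search.csv"
        study.selection.per_config_table.to_csv(sel, index=False,
                                                float_format=_FLOAT_FMT)
        paths["grid_search"] = sel

    best = {}
    for metric in METRIC_DIRECTIONS:
        b, flagged = study.best_models(metric)
        best[metric] = {"best": b, "indistinguishable": sorted(flagged)}

    manifest = {
        "chemuq_version": __version__,
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_seconds": elapsed,
        "seeds": _jsonable(study.seeds),
        "best_per_metric": best,
        "config": _jsonable(dataclasses.asdict(config)) if config else None,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
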
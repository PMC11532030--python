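"""Seeded end-to-end orchestration: clean → featurize → train → ensemble → evaluate.

The pipeline reproduces the study design at configurable budgets:

1. clean the kcat table and transform targets to log10;
2. split into train/test (honouring explicit labels when present);
3. featurize sequences and reactions into the six feature blocks;
4. z-score the embedding blocks with parameters fitted on training rows
   only (binary fingerprint blocks pass through unchanged by default);
5. hyperparameter search for the boosted-tree and CNN regressors;
6. train the top-k configurations of each family on a fit slice, fit
   simplex ensemble weights on a held-out validation slice of the
   training data (never on test);
7. evaluate single-best and weighted-ensemble predictions on the test
   set, emitting R²/MSE/Pearson reports plus per-point scatter data.

All stochastic stages draw from explicit seeds, so a rerun with the same
config reproduces the same reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from . import gbt as gbt_mod
from .data import BINARY_BLOCKS, KcatDataset
from .ensemble import EnsembleWeights, PredictionPanel, optimize_weights, select_top_models, weighted_average
from .errors import ParameterError, StageError
from .io import read_kcat_table
from .metrics import EvaluationReport, evaluate_predictions
from .preprocess import clean_dataset, fit_apply_zscore, split_dataset, transform_targets
from .synthetic import SyntheticSpec, generate_dataset

DEFAULT_GBT_BLOCKS = (
    "emb_base",
    "emb_finetuned",
    "fp_structural",
    "fp_differential",
    "fp_difference",
)
DEFAULT_CNN_BLOCKS = ("emb_combined", "fp_differential", "fp_difference")


@dataclass
class PipelineConfig:
    """Everything a run needs; every stochastic stage has an explicit seed."""

    synthetic: SyntheticSpec | None = None
    table_path: str | None = None
    outlier_z: float = 3.0
    test_frac: float = 0.2
    val_frac: float = 0.15
    gbt_blocks: tuple[str, ...] = DEFAULT_GBT_BLOCKS
    cnn_blocks: tuple[str, ...] = DEFAULT_CNN_BLOCKS
    gbt_trials: int = 10
    cnn_trials: int = 3
    k_folds: int = 3
    ensemble_k: int = 3
    cnn_max_epochs: int = 20
    normalize_fingerprints: bool = False
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.table_path is None):
            raise ParameterError(
                "config needs exactly one input: a synthetic spec or a table path"
            )
        if self.ensemble_k < 1:
            raise ParameterError("ensemble_k must be ≥ 1")


@dataclass
class PipelineResult:
    reports: dict[str, EvaluationReport]
    weights: dict[str, EnsembleWeights]
    models: dict[str, list]
    scatter: pd.DataFrame
    cleaning_report: object
    trial_logs: dict[str, gbt_mod.TrialLog] = field(default_factory=dict)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 — rewrap with the stage name
        raise StageError(name, exc) from exc


def _normalized_matrices(store, train_rows: np.ndarray, normalize_fp: bool):
    """Z-score embedding blocks on the training rows; fingerprints optional."""
    out: dict[str, np.ndarray] = {}
    for name, block in store.blocks.items():
        X = block.matrix.astype(float)
        if name in BINARY_BLOCKS and not normalize_fp:
            out[name] = X
        else:
            _, _, params = fit_apply_zscore(X[train_rows], fitted_on="train")
            out[name] = params.apply(X)
    return out


def _family_models_and_panels(
    family: str,
    cfg: PipelineConfig,
    feats: dict[str, np.ndarray],
    y: np.ndarray,
    fit_rows: np.ndarray,
    val_rows: np.ndarray,
    test_rows: np.ndarray,
):
    """Search, train top-k members, and collect val/test prediction panels."""
    if family == "gbt":
        X = np.hstack([feats[name] for name in cfg.gbt_blocks])
        best, log = gbt_mod.cross_validated_search(
            X[fit_rows],
            y[fit_rows],
            n_trials=cfg.gbt_trials,
            k_folds=cfg.k_folds,
            seed=cfg.seed + 11,
        )
        k = min(cfg.ensemble_k, len(log.trials))
        top = select_top_models(log.losses, k=k)
        configs = [log.trials[i][0] for i in top]
        models = [
            gbt_mod.train_gbt(X[fit_rows], y[fit_rows], c, seed=cfg.seed + 11)
            for c in configs
        ]
        val_preds = np.column_stack([m.predict(X[val_rows]) for m in models])
        test_preds = np.column_stack([m.predict(X[test_rows]) for m in models])
    else:
        tensor = _stack(feats, cfg.cnn_blocks)
        # keep sampled batch sizes feasible for the fit slice
        space = cnn_mod.CNNSearchSpace(
            batch_size=(8, max(8, min(128, len(fit_rows) // 2)))
        )
        log, ranked = cnn_mod.random_search_cnn(
            tensor[fit_rows],
            y[fit_rows],
            space=space,
            n_trials=cfg.cnn_trials,
            seed=cfg.seed + 23,
            max_epochs=cfg.cnn_max_epochs,
        )
        if not ranked:
            raise ParameterError("every CNN trial failed to train")
        k = min(cfg.ensemble_k, len(ranked))
        configs = ranked[:k]
        models = [
            cnn_mod.train_cnn(
                tensor[fit_rows], y[fit_rows], c, seed=cfg.seed + 23,
                max_epochs=cfg.cnn_max_epochs,
            )
            for c in configs
        ]
        val_preds = np.column_stack([m.predict(tensor[val_rows]) for m in models])
        test_preds = np.column_stack([m.predict(tensor[test_rows]) for m in models])
    ids = [f"{family}-{j}" for j in range(len(models))]
    panel = PredictionPanel(
        preds=val_preds, model_ids=ids, y_true=y[val_rows], fitted_on="validation"
    )
    return models, log, panel, test_preds


def _stack(feats: dict[str, np.ndarray], names: tuple[str, ...]) -> np.ndarray:
    length = max(feats[n].shape[1] for n in names)
    n_samples = next(iter(feats.values())).shape[0]
    tensor = np.zeros((n_samples, len(names), length))
    for c, name in enumerate(names):
        tensor[:, c, : feats[name].shape[1]] = feats[name]
    return tensor


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full study pipeline; see the module docstring."""
    if cfg.synthetic is not None:
        ds, store, _truth = _stage("simulate", generate_dataset, cfg.synthetic)
    else:
        ds = _stage("read", read_kcat_table, cfg.table_path)
        store = None

    ds, cleaning = _stage("clean", clean_dataset, ds, cfg.outlier_z)
    if store is not None:
        store = store.subset(ds.record_ids)
    y = _stage("transform", transform_targets, ds)

    if ds.has_split_labels:
        train_ids, test_ids = _stage("split", split_dataset, ds)
    else:
        train_ids, test_ids = _stage(
            "split", split_dataset, ds, cfg.test_frac, cfg.seed + 5
        )

    if store is None:
        from .embeddings import assemble_feature_store

        store = _stage("featurize", assemble_feature_store, ds)

    index = {rid: i for i, rid in enumerate(ds.record_ids)}
    train_rows = np.array([index[r] for r in train_ids])
    test_rows = np.array([index[r] for r in test_ids])
    rng = np.random.default_rng(cfg.seed + 7)
    perm = rng.permutation(len(train_rows))
    n_val = max(1, int(round(cfg.val_frac * len(train_rows))))
    val_rows = train_rows[perm[:n_val]]
    fit_rows = train_rows[perm[n_val:]]

    feats = _stage(
        "normalize", _normalized_matrices, store, train_rows, cfg.normalize_fingerprints
    )

    reports: dict[str, EvaluationReport] = {}
    weights: dict[str, EnsembleWeights] = {}
    models: dict[str, list] = {}
    logs: dict[str, gbt_mod.TrialLog] = {}
    scatter_rows = []

    for family in ("gbt", "cnn"):
        fam_models, log, panel, test_preds = _stage(
            f"train-{family}",
            _family_models_and_panels,
            family, cfg, feats, y, fit_rows, val_rows, test_rows,
        )
        w = _stage(f"ensemble-{family}", optimize_weights, panel)
        # dominance on the fitting (validation) panel is mathematically forced
        assert w.loss_at_optimum <= panel.member_losses().min() + 1e-12

        single_test = test_preds[:, 0]  # rank-1 model by validation loss
        ens_test = weighted_average(test_preds, w)
        reports[f"{family}-single"] = evaluate_predictions(y[test_rows], single_test)
        reports[f"{family}-ensemble"] = evaluate_predictions(y[test_rows], ens_test)
        weights[family] = w
        models[family] = fam_models
        logs[family] = log
        for method, pred in ((f"{family}-single", single_test), (f"{family}-ensemble", ens_test)):
            for rid, yt, yp in zip(test_ids, y[test_rows], pred):
                scatter_rows.append(
                    {"method": method, "record_id": rid, "y_true": yt, "y_pred": yp}
                )

    scatter = pd.DataFrame(scatter_rows)
    result = PipelineResult(
        reports=reports,
        weights=weights,
        models=models,
        scatter=scatter,
        cleaning_report=cleaning,
        trial_logs=logs,
    )
    if cfg.output_dir is not None:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: PipelineConfig, result: PipelineResult) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reports.json").write_text(
        json.dumps({k: r.as_dict() for k, r in result.reports.items()}, indent=2)
    )
    (out / "weights.json").write_text(
        json.dumps(
            {
                k: {"w": w.w.tolist(), "loss_at_optimum": w.loss_at_optimum}
                for k, w in result.weights.items()
            },
            indent=2,
        )
    )
    result.scatter.to_csv(out / "scatter.csv", index=False)
    cr = result.cleaning_report
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "cleaning": {
                    "n_input": cr.n_input,
                    "n_missing_removed": cr.n_missing_removed,
                    "n_duplicates_merged": cr.n_duplicates_merged,
                    "n_outliers_removed": cr.n_outliers_removed,
                    "n_output": cr.n_output,
                },
                "gbt_blocks": list(cfg.gbt_blocks),
                "cnn_blocks": list(cfg.cnn_blocks),
                "ensemble_k": cfg.ensemble_k,
            },
            indent=2,
        )
    )
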
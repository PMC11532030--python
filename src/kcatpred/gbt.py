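"""Gradient-boosted-tree regressor with cross-validated random search.

The search space follows the study's stated ranges: learning rate
0.01–1, tree depth 4–12, L2 penalty 0–5, max delta step 0–5, minimum
child weight 0.1–15, and 20–200 boosting rounds. Each sampled
configuration is scored by mean validation MSE over k seeded folds; the
fold partition is fixed across trials so configurations compete on
identical data. Training is single-threaded and seeded, which makes the
fitted booster bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from sklearn.model_selection import KFold

from .errors import DataError, ParameterError, ShapeError

GBT_BOUNDS = {
    "learning_rate": (0.01, 1.0),
    "max_depth": (4, 12),
    "reg_lambda": (0.0, 5.0),
    "max_delta_step": (0.0, 5.0),
    "min_child_weight": (0.1, 15.0),
    "num_rounds": (20, 200),
}


@dataclass(frozen=True)
class GBTSearchSpace:
    """Hyperparameter ranges; integers for max_depth and num_rounds."""

    learning_rate: tuple[float, float] = GBT_BOUNDS["learning_rate"]
    max_depth: tuple[int, int] = GBT_BOUNDS["max_depth"]
    reg_lambda: tuple[float, float] = GBT_BOUNDS["reg_lambda"]
    max_delta_step: tuple[float, float] = GBT_BOUNDS["max_delta_step"]
    min_child_weight: tuple[float, float] = GBT_BOUNDS["min_child_weight"]
    num_rounds: tuple[int, int] = GBT_BOUNDS["num_rounds"]

    def __post_init__(self) -> None:
        for name in GBT_BOUNDS:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name}: min {lo} > max {hi}")


def sample_gbt_config(space: GBTSearchSpace, seed: int) -> dict:
    """One uniform draw from the space; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return {
        "learning_rate": float(rng.uniform(*space.learning_rate)),
        "max_depth": int(rng.integers(space.max_depth[0], space.max_depth[1] + 1)),
        "reg_lambda": float(rng.uniform(*space.reg_lambda)),
        "max_delta_step": float(rng.uniform(*space.max_delta_step)),
        "min_child_weight": float(rng.uniform(*space.min_child_weight)),
        "num_rounds": int(rng.integers(space.num_rounds[0], space.num_rounds[1] + 1)),
    }


@dataclass
class TrialLog:
    """Every (config, validation loss, seed) evaluated during a search."""

    trials: list[tuple[dict, float, int]] = field(default_factory=list)

    def record(self, config: dict, loss: float, seed: int) -> None:
        self.trials.append((config, float(loss), seed))

    @property
    def losses(self) -> list[float]:
        return [t[1] for t in self.trials]

    @property
    def best_index(self) -> int:
        losses = self.losses
        return min(range(len(losses)), key=lambda i: (losses[i], i))

    def ranked(self) -> list[int]:
        """Trial indices sorted by loss ascending, ties to lower index."""
        losses = self.losses
        return sorted(range(len(losses)), key=lambda i: (losses[i], i))

    def as_json(self) -> list[dict]:
        return [
            {"config": c, "val_loss": l, "seed": s} for c, l, s in self.trials
        ]


@dataclass
class TrainedRegressor:
    """A fitted model with its config, seed and training log."""

    kind: str
    config: dict
    seed: int
    training_log: list[float]
    _predict_fn: object = None

    def predict(self, X) -> np.ndarray:
        out = np.asarray(self._predict_fn(X), dtype=float)
        if not np.isfinite(out).all():
            raise DataError("model produced non-finite predictions")
        return out


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ShapeError(f"X {X.shape} does not align with y of length {len(y)}")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise DataError("non-finite values in X or y")
    return X, y


def train_gbt(X: np.ndarray, y: np.ndarray, config: dict, seed: int = 0) -> TrainedRegressor:
    """Fit a seeded, single-threaded booster with the given configuration."""
    X, y = _check_xy(X, y)
    if X.shape[0] < 2:
        raise ParameterError("need at least 2 training rows")
    params = {
        "objective": "reg:squarederror",
        "learning_rate": config["learning_rate"],
        "max_depth": config["max_depth"],
        "reg_lambda": config["reg_lambda"],
        "max_delta_step": config["max_delta_step"],
        "min_child_weight": config["min_child_weight"],
        "seed": seed,
        "nthread": 1,
        "tree_method": "hist",
    }
    dtrain = xgb.DMatrix(X, label=y)
    evals_result: dict = {}
    booster = xgb.train(
        params,
        dtrain,
        num_boost_round=config["num_rounds"],
        evals=[(dtrain, "train")],
        evals_result=evals_result,
        verbose_eval=False,
    )
    log = [float(v) ** 2 for v in evals_result["train"]["rmse"]]  # MSE per round

    def _predict(Xnew):
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.ndim != 2 or Xnew.shape[1] != X.shape[1]:
            raise ShapeError(
                f"prediction matrix has shape {Xnew.shape}, trained on "
                f"{X.shape[1]} features"
            )
        if Xnew.shape[0] == 0:
            return np.empty(0)
        return booster.predict(xgb.DMatrix(Xnew))

    return TrainedRegressor(
        kind="gbt", config=dict(config), seed=seed, training_log=log, _predict_fn=_predict
    )


def cross_validated_search(
    X: np.ndarray,
    y: np.ndarray,
    space: GBTSearchSpace | None = None,
    n_trials: int = 50,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, TrialLog]:
    """Random search scored by mean validation MSE over fixed k folds."""
    X, y = _check_xy(X, y)
    space = space or GBTSearchSpace()
    if n_trials < 1:
        raise ParameterError("n_trials must be ≥ 1")
    if k_folds < 2 or k_folds > X.shape[0]:
        raise ParameterError(
            f"k_folds must be in [2, n_rows]; got {k_folds} with {X.shape[0]} rows"
        )
    folds = list(KFold(n_splits=k_folds, shuffle=True, random_state=seed).split(X))
    log = TrialLog()
    for t in range(n_trials):
        trial_seed = seed + 1000 * t + 1
        config = sample_gbt_config(space, trial_seed)
        fold_mse = []
        for train_idx, val_idx in folds:
            model = train_gbt(X[train_idx], y[train_idx], config, seed=trial_seed)
            pred = model.predict(X[val_idx])
            fold_mse.append(float(np.mean((pred - y[val_idx]) ** 2)))
        log.record(config, float(np.mean(fold_mse)), trial_seed)
    best_config = log.trials[log.best_index][0]
    return dict(best_config), log
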
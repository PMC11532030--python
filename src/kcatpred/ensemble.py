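"""Simplex-constrained weighted-mean ensembling.

Instead of averaging member predictions with equal weight, the ensemble
weight vector w is fitted by minimizing the loss of the combined
prediction P·w against the truth, subject to w lying on the probability
simplex (wᵢ ≥ 0, Σwᵢ = 1). With MSE loss this is a convex quadratic
program, so the optimum is global; the solver nonetheless multi-starts
from the uniform point and every vertex as insurance and keeps the best
feasible iterate, which also guarantees the dominance property: the
optimized loss never exceeds the uniform-mean loss or any single
member's loss (all are feasible points).

For independent unbiased members the optimal weights approach
inverse-variance weights, w_j ∝ 1/σ_j² — the classical precision
weighting this procedure generalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import DataError, ParameterError, ShapeError


@dataclass
class PredictionPanel:
    """n × m member predictions with the matching truth vector."""

    preds: np.ndarray
    model_ids: list[str]
    y_true: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.preds = np.asarray(self.preds, dtype=float)
        self.y_true = np.asarray(self.y_true, dtype=float)
        if self.preds.ndim != 2:
            raise ShapeError("preds must be an n × m matrix")
        n, m = self.preds.shape
        if n < 1 or m < 1:
            raise ParameterError("panel needs at least one sample and one member")
        if len(self.y_true) != n:
            raise ShapeError(f"y_true length {len(self.y_true)} != {n} rows")
        if len(self.model_ids) != m:
            raise ShapeError(f"{len(self.model_ids)} model ids != {m} columns")
        if not np.isfinite(self.preds).all() or not np.isfinite(self.y_true).all():
            raise DataError("panel contains non-finite values")

    @property
    def n_models(self) -> int:
        return self.preds.shape[1]

    def member_losses(self) -> np.ndarray:
        """Per-member MSE against the truth."""
        return np.mean((self.preds - self.y_true[:, None]) ** 2, axis=0)


@dataclass
class EnsembleWeights:
    """A simplex weight vector with the loss it attains."""

    w: np.ndarray
    loss_at_optimum: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if abs(self.w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights sum to {self.w.sum()}, expected 1")
        if (self.w < -1e-12).any() or (self.w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")


def _panel_mse(preds: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    r = preds @ w - y
    return float(r @ r) / len(y)


def _project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (Held et al. style)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def optimize_weights(panel: PredictionPanel, loss: str = "mse") -> EnsembleWeights:
    """Fit simplex weights minimizing the ensemble loss on the panel.

    Deterministic given the panel. The returned weights are exactly
    feasible (projected and renormalized) and are guaranteed not to lose
    to the uniform mean or to any single member on this panel.
    """
    if loss != "mse":
        raise ParameterError(f"unsupported loss {loss!r}")
    P, y = panel.preds, panel.y_true
    m = panel.n_models
    if m == 1:
        return EnsembleWeights(
            w=np.array([1.0]),
            loss_at_optimum=_panel_mse(P, y, np.array([1.0])),
            diagnostics={"solver": "trivial"},
        )

    # Feasible reference points: uniform mean and every vertex.
    starts = [np.full(m, 1.0 / m)]
    starts += [np.eye(m)[j] for j in range(m)]

    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * m
    A = P.T @ P / len(y)
    b = P.T @ y / len(y)

    def objective(w):
        return float(w @ A @ w - 2.0 * b @ w + y @ y / len(y))

    def gradient(w):
        return 2.0 * (A @ w - b)

    best_w, best_loss, n_iters = None, np.inf, []
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=gradient,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        w = _project_to_simplex(res.x)
        w = w / w.sum()
        cur = _panel_mse(P, y, w)
        n_iters.append(int(res.nit))
        if cur < best_loss:
            best_loss, best_w = cur, w
    # Feasible fallbacks guarantee dominance even if the solver stalls.
    for w0 in starts:
        cur = _panel_mse(P, y, w0)
        if cur < best_loss:
            best_loss, best_w = cur, w0
    return EnsembleWeights(
        w=best_w,
        loss_at_optimum=best_loss,
        diagnostics={"solver": "slsqp-multistart", "n_starts": len(starts), "iters": n_iters},
    )


def weighted_average(preds: np.ndarray, weights: EnsembleWeights | np.ndarray) -> np.ndarray:
    """Combined prediction Σ_j w_j · preds[:, j]."""
    w = weights.w if isinstance(weights, EnsembleWeights) else np.asarray(weights, float)
    preds = np.asarray(preds, dtype=float)
    if preds.ndim != 2 or preds.shape[1] != len(w):
        raise ShapeError(
            f"preds has shape {preds.shape}, weights have length {len(w)}"
        )
    return preds @ w


def select_top_models(trial_scores, k: int = 3) -> list[int]:
    """Indices of the k smallest validation losses; ties break to lower index."""
    scores = list(trial_scores)
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if k > len(scores):
        raise ParameterError(f"k={k} exceeds the {len(scores)} scored models")
    order = sorted(range(len(scores)), key=lambda i: (scores[i], i))
    return order[:k]
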
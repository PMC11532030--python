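"""Evaluation metrics on the log10-kcat scale: R², MSE, Pearson r.

R² is the coefficient of determination 1 − SSE/SST (not the squared
correlation): it can be negative for a predictor worse than the mean.
Degenerate cases carry an explicit undefined marker (NaN) rather than an
arbitrary number: Pearson r is undefined when either vector has zero
variance, and R² is undefined when SST = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import NamingError, ParameterError, ShapeError


@dataclass
class EvaluationReport:
    """R², MSE and Pearson r for one prediction set, on a stated scale."""

    r2: float
    mse: float
    pearson: float
    n: int
    target_scale: str = "log10"

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "mse": self.mse,
            "pearson": self.pearson,
            "n": self.n,
            "target_scale": self.target_scale,
        }


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, target_scale: str = "log10"
) -> EvaluationReport:
    """Compute MSE, R² = 1 − SSE/SST, and sample Pearson correlation."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ShapeError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    n = len(y_true)
    if n == 0:
        raise ParameterError("cannot evaluate zero predictions")

    residual = y_true - y_pred
    mse = float(residual @ residual) / n
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - (residual @ residual) / sst if sst > 0 else float("nan")

    sd_t = y_true.std()
    sd_p = y_pred.std()
    if sd_t == 0 or sd_p == 0:
        pearson = float("nan")
    else:
        pearson = float(
            np.mean((y_true - y_true.mean()) * (y_pred - y_pred.mean())) / (sd_t * sd_p)
        )
    return EvaluationReport(r2=r2, mse=mse, pearson=pearson, n=n, target_scale=target_scale)


def comparison_report(
    reports: dict[str, EvaluationReport], json_path: str | Path | None = None
) -> str:
    """Format named reports as a metric × method table (2-decimal cells).

    Optionally writes the unrounded values to ``json_path`` alongside.
    Duplicate method names cannot occur in a dict, but empty input and
    blank names are rejected.
    """
    if not reports:
        raise ParameterError("need at least one report")
    names = list(reports)
    if len(set(names)) != len(names) or any(not n for n in names):
        raise NamingError("method names must be unique and non-empty")

    metrics = [("R2 score", "r2"), ("Mean square error", "mse"), ("Pearson coefficient", "pearson")]
    widths = [max(len(m[0]) for m in metrics)] + [max(len(n), 6) for n in names]
    header = "  ".join(["Metric".ljust(widths[0])] + [n.rjust(w) for n, w in zip(names, widths[1:])])
    lines = [header, "-" * len(header)]
    for label, attr in metrics:
        cells = [f"{getattr(reports[n], attr):.2f}".rjust(w) for n, w in zip(names, widths[1:])]
        lines.append("  ".join([label.ljust(widths[0])] + cells))
    table = "\n".join(lines)

    if json_path is not None:
        payload = {name: rep.as_dict() for name, rep in reports.items()}
        Path(json_path).write_text(json.dumps(payload, indent=2))
    return table
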
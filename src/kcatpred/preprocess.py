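"""Cleaning, target transformation, normalization and splitting.

Cleaning removes records with missing fields, merges duplicates sharing
an identical (sequence, reaction) pair into one record whose kcat is the
geometric mean (kcat is a multiplicative quantity), and drops log10-kcat
outliers beyond a z-score threshold computed on the post-merge set.
Targets are modelled as y = log10(kcat); all downstream metrics are on
this scale. Z-score normalization is fitted on the training rows only
(population standard deviation, divisor n) and applied unchanged to any
other split; constant columns map to zero rather than dividing by zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import KcatDataset, KcatRecord
from .errors import DataError, ParameterError, ShapeError

logger = logging.getLogger(__name__)


@dataclass
class CleaningReport:
    """Accounting of every record removed or merged during cleaning."""

    n_input: int
    n_missing_removed: int
    n_duplicates_merged: int
    n_outliers_removed: int
    n_output: int

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_missing_removed
            - self.n_duplicates_merged
            - self.n_outliers_removed
        )
        if self.n_output != expected:
            raise ValueError(
                f"cleaning counts do not reconcile: {self.n_output} != {expected}"
            )


@dataclass
class NormalizationParams:
    """Per-column mean/sd fitted on one split, reused everywhere else."""

    means: np.ndarray
    sds: np.ndarray
    fitted_on: str = "train"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise ShapeError("means and sds must be 1-D arrays of equal length")
        if (self.sds < 0).any():
            raise ValueError("standard deviations must be nonnegative")

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.means.shape[0]:
            raise ShapeError(
                f"matrix has {X.shape[1]} columns, params have {self.means.shape[0]}"
            )
        safe_sd = np.where(self.sds == 0, 1.0, self.sds)
        out = (X - self.means) / safe_sd
        out[:, self.sds == 0] = 0.0
        return out


def clean_dataset(
    ds: KcatDataset, outlier_z: float = 3.0
) -> tuple[KcatDataset, CleaningReport]:
    """Remove missing records, merge duplicates, drop log-scale outliers.

    Order of operations: (1) drop records with missing sequence, reaction
    or kcat; (2) merge identical (sequence, reaction) groups into the
    first-seen record with the geometric-mean kcat; (3) drop records
    whose log10-kcat z-score (computed on the post-merge set) exceeds
    ``outlier_z`` in magnitude. Emits a warning rather than silently
    succeeding if nothing survives.
    """
    if len(ds) == 0:
        raise ParameterError("cannot clean an empty dataset")

    survivors = [
        r for r in ds if r.kcat is not None and r.sequence and r.reaction
    ]
    n_missing = len(ds) - len(survivors)

    groups: dict[tuple[str, str], list[KcatRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in survivors:
        key = (r.sequence, r.reaction)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    merged: list[KcatRecord] = []
    n_merged_away = 0
    for key in order:
        members = groups[key]
        first = members[0]
        if len(members) == 1:
            merged.append(first)
        else:
            n_merged_away += len(members) - 1
            geo = float(10 ** np.mean([np.log10(m.kcat) for m in members]))
            merged.append(
                KcatRecord(
                    record_id=first.record_id,
                    sequence=first.sequence,
                    reaction=first.reaction,
                    kcat=geo,
                    split_label=first.split_label,
                    source=first.source,
                )
            )

    if merged:
        logk = np.log10([r.kcat for r in merged])
        sd = logk.std()
        z = (logk - logk.mean()) / sd if sd > 0 else np.zeros_like(logk)
        keep = np.abs(z) <= outlier_z
    else:
        keep = np.array([], dtype=bool)
    cleaned = [r for r, k in zip(merged, keep) if k]
    n_outliers = len(merged) - len(cleaned)

    if not cleaned:
        warnings.warn("cleaning removed every record", stacklevel=2)
    report = CleaningReport(
        n_input=len(ds),
        n_missing_removed=n_missing,
        n_duplicates_merged=n_merged_away,
        n_outliers_removed=n_outliers,
        n_output=len(cleaned),
    )
    return KcatDataset(records=cleaned, provenance=ds.provenance), report


def transform_targets(ds: KcatDataset) -> np.ndarray:
    """y_i = log10(kcat_i); raises :class:`DataError` naming any bad record."""
    for r in ds:
        if r.kcat is None or r.kcat <= 0:
            raise DataError(
                f"record {r.record_id!r}: kcat must be present and > 0 "
                f"for the log10 transform (got {r.kcat})"
            )
    return np.log10([r.kcat for r in ds])


def inverse_transform_targets(y: np.ndarray) -> np.ndarray:
    """Back from log10 space to kcat in s⁻¹."""
    return np.power(10.0, np.asarray(y, dtype=float))


def fit_apply_zscore(
    train_X: np.ndarray, other_X: np.ndarray | None = None, fitted_on: str = "train"
) -> tuple[np.ndarray, np.ndarray | None, NormalizationParams]:
    """Z-score both matrices with parameters fitted on ``train_X`` only."""
    train_X = np.asarray(train_X, dtype=float)
    if train_X.ndim != 2 or train_X.shape[0] < 2:
        raise ParameterError("train matrix must be 2-D with at least 2 rows")
    if other_X is not None:
        other_X = np.asarray(other_X, dtype=float)
        if other_X.shape[1] != train_X.shape[1]:
            raise ShapeError(
                f"column mismatch: train {train_X.shape[1]} vs other {other_X.shape[1]}"
            )
    params = NormalizationParams(
        means=train_X.mean(axis=0), sds=train_X.std(axis=0), fitted_on=fitted_on
    )
    return (
        params.apply(train_X),
        params.apply(other_X) if other_X is not None else None,
        params,
    )


def split_dataset(
    ds: KcatDataset,
    test_frac: float | None = None,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Partition record ids into (train, test).

    Datasets carrying explicit split labels are honoured verbatim and
    must not also request a fraction; otherwise a seeded uniform random
    split of the stated fraction is drawn.
    """
    if ds.has_split_labels:
        if test_frac is not None:
            raise ParameterError(
                "dataset carries split labels; do not also pass test_frac"
            )
        train = [r.record_id for r in ds if r.split_label == "train"]
        test = [r.record_id for r in ds if r.split_label == "test"]
        return train, test
    if test_frac is None or not (0 < test_frac < 1):
        raise ParameterError(f"test_frac must be in (0, 1), got {test_frac}")
    rng = np.random.default_rng(seed)
    ids = ds.record_ids
    n_test = int(round(len(ids) * test_frac))
    n_test = min(max(n_test, 1), len(ids) - 1)
    perm = rng.permutation(len(ids))
    test_idx = set(perm[:n_test].tolist())
    train = [rid for i, rid in enumerate(ids) if i not in test_idx]
    test = [rid for i, rid in enumerate(ids) if i in test_idx]
    return train, test
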
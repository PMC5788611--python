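"""Random-forest feature-importance estimation and threshold selection.

The two-step protocol: (1) estimate a feature importance score (FIS) for
every column of the feature matrix as the ensemble-averaged Gini
(mean-decrease-in-impurity) importance of random forests grown on the
training part of each stratified cross-validation round, with the
variables-tried-per-split drawn uniformly from 1..min(100, D) per round;
(2) derive nested candidate subsets by sweeping an FIS cut-off and keep
the subset whose downstream cross-validated MCC peaks.

FIS vectors are normalized to sum to 1, so a cut-off like 0.0003 is a
share of total importance. Rank stability, not the absolute values, is
the contract: tree counts and fold counts are tunable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .metrics import MetricsReport

__all__ = [
    "FeatureImportance",
    "FeatureSubset",
    "estimate_fis",
    "select_candidates",
    "threshold_sweep",
    "select_best_model",
]


@dataclasses.dataclass
class FeatureImportance:
    """Per-feature importance scores with the protocol that produced them."""

    fis: pd.Series  # indexed by feature name, original column order
    n_trees: int
    folds: int
    seed: int

    def sorted(self) -> pd.Series:
        """Scores sorted descending (ties keep column order)."""
        return self.fis.sort_values(ascending=False, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        return self.sorted().rename("fis").rename_axis("feature").reset_index()


@dataclasses.dataclass
class FeatureSubset:
    """Features with FIS ≥ threshold, in original column order."""

    threshold: float
    names: list[str]

    @property
    def size(self) -> int:
        return len(self.names)


def estimate_fis(
    X: pd.DataFrame,
    y: Sequence[int],
    n_trees: int = 10_000,
    folds: int = 10,
    seed: int = 0,
    max_features_cap: int = 100,
) -> FeatureImportance:
    """Estimate FIS by averaging forest impurity importances over CV rounds.

    Per stratified round a forest of ``n_trees`` is grown on the training
    part with ``max_features`` drawn uniformly from 1..min(cap, D); the
    per-forest importances (which sum to 1) are averaged across rounds and
    renormalized. Deterministic given ``seed``.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("FIS estimation requires two classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    D = X.shape[1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    acc = np.zeros(D)
    n_rounds = 0
    for round_idx, (train_idx, _) in enumerate(skf.split(X, y)):
        mtry = int(rng.integers(1, min(max_features_cap, D) + 1))
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31)),
            n_jobs=1,
        )
        forest.fit(X.iloc[train_idx].to_numpy(), y[train_idx])
        acc += forest.feature_importances_
        n_rounds += 1
    acc /= n_rounds
    total = acc.sum()
    if total > 0:
        acc = acc / total
    return FeatureImportance(
        fis=pd.Series(acc, index=X.columns, dtype=float),
        n_trees=n_trees,
        folds=folds,
        seed=seed,
    )


def select_candidates(
    fis: FeatureImportance, threshold: float = 0.0003
) -> FeatureSubset:
    """Features with FIS ≥ threshold, preserving original column order."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    names = list(fis.fis.index[fis.fis >= threshold])
    if not names:
        warnings.warn(
            f"no feature reaches FIS threshold {threshold}", stacklevel=2
        )
    return FeatureSubset(threshold=threshold, names=names)


def threshold_sweep(
    fis: FeatureImportance,
    start: float = 0.0003,
    stop: float = 0.0021,
    step: float = 0.0001,
) -> list[FeatureSubset]:
    """One subset per cut-off on an inclusive grid (default: 19 cut-offs).

    Subsets are nested: a higher cut-off always selects a subset of a
    lower one, so sizes are non-increasing along the grid.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if start > stop:
        raise ValueError("start must be <= stop")
    n = int(round((stop - start) / step)) + 1
    grid = [start + i * step for i in range(n)]
    if grid[-1] > stop + 1e-12:
        grid = grid[:-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [select_candidates(fis, t) for t in grid]


def select_best_model(
    cv_results: Sequence[tuple[FeatureSubset, MetricsReport]],
) -> FeatureSubset:
    """Subset with the highest cross-validated MCC; ties go to the smaller set."""
    if not cv_results:
        raise ValueError("empty result list")
    return max(cv_results, key=lambda sr: (sr[1].mcc, -sr[0].size))[0]
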
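"""Classifier training under repeated stratified cross-validation.

Four learner families are supported — RBF-kernel SVM, random forest,
extremely randomized trees (ET) and k-nearest neighbours — each tuned by
an exhaustive grid search that maximizes cross-validated MCC. The
evaluation protocol is five-times-repeated stratified 10-fold CV with
hyperparameters tuned on the nine training folds of every split (fully
nested, so no selection leakage), mean metrics across repeats, and the
median of the chosen hyperparameters reported as the stable final values;
the final deployable model is refit on all data with those medians.

The RBF-SVM grid spans C = 2^-15..2^10 and gamma = 2^-10..2^10 at integer
log2 steps (546 points); an optional second-stage local refinement at
factor-2^0.25 resolution is available since published optima are not
always on the integer-exponent grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import statistics
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .metrics import MetricsReport, confusion, metrics_report, roc_auc

__all__ = [
    "FAMILIES",
    "HYBRIDS",
    "ModelSpec",
    "TrainedModel",
    "CVResult",
    "ContractError",
    "default_grid",
    "grid_search_svm",
    "repeated_cv",
    "fit_final",
    "predict",
    "enumerate_experiment",
]

FAMILIES = ("svm_rbf", "random_forest", "extra_trees", "knn")

#: hybrid feature-block combinations evaluated alongside single blocks
HYBRIDS: dict[str, tuple[str, ...]] = {
    "H1": ("MNC", "DNC"),
    "H2": ("MNC", "DNC", "TNC"),
    "H3": ("MNC", "DNC", "TeNC"),
    "H4": ("MNC", "DNC", "TeNC", "PNC", "DPCP"),
    "H5": ("DPCP", "TPCP"),
    "H6": ("MNC", "DNC", "TeNC", "PNC", "TPCP"),
    "H7": ("MNC", "DNC", "TNC", "TeNC", "PNC", "DPCP", "TPCP"),
}


class ContractError(ValueError):
    """Feature columns do not match a trained model's feature contract."""


def default_grid(family: str) -> dict[str, list]:
    """Family-specific default hyperparameter grid."""
    if family == "svm_rbf":
        return {
            "C": [2.0**e for e in range(-15, 11)],
            "gamma": [2.0**e for e in range(-10, 11)],
        }
    if family == "knn":
        return {"n_neighbors": list(range(1, 26, 2))}
    if family in ("random_forest", "extra_trees"):
        return {"n_estimators": [100, 500, 1000], "max_features": ["sqrt", 0.1, 0.3]}
    raise ValueError(f"unknown family {family!r}; valid: {FAMILIES}")


@dataclasses.dataclass
class ModelSpec:
    """A learner family plus its hyperparameter search grid."""

    family: str
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.grid is None:
            self.grid = default_grid(self.family)
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")
        if self.family == "svm_rbf" and not {"C", "gamma"} <= set(self.grid):
            raise ValueError("svm_rbf grid must cover C and gamma")


@dataclasses.dataclass
class TrainedModel:
    """A fitted classifier with its feature-name contract and provenance."""

    family: str
    estimator: object
    params: dict
    feature_names: list[str]
    seed: int
    data_hash: str


@dataclasses.dataclass
class CVResult:
    """Outcome of repeated stratified CV.

    ``oof`` holds one out-of-fold prediction per sample per repeat;
    ``report`` is the mean of the per-repeat metric reports (so its Pt/Py
    are means of per-repeat Pt/Py, not functions of the mean Sn/Sp).
    """

    oof: pd.DataFrame
    per_repeat: list[MetricsReport]
    report: MetricsReport
    chosen_params: list[dict]
    median_params: dict
    spec: ModelSpec
    repeats: int
    folds: int
    seed: int


def _make_estimator(family: str, params: Mapping, seed: int, proba: bool = True):
    if family == "svm_rbf":
        base = SVC(kernel="rbf", random_state=seed, C=params["C"], gamma=params["gamma"])
        if not proba:
            return base
        # Platt-scaled probabilities; the calibration CV runs inside the
        # training partition only, so held-out folds stay untouched
        return CalibratedClassifierCV(base, method="sigmoid", cv=2, ensemble=False)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown family {family!r}")


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    """All grid combinations, ascending in sorted-key order (ties in the
    MCC search then resolve to the smallest values, e.g. smallest C then
    smallest gamma for the SVM)."""
    keys = sorted(grid)
    points: list[dict] = [{}]
    for key in keys:
        points = [dict(p, **{key: v}) for p in points for v in grid[key]]
    return points


def _cv_mcc(X: np.ndarray, y: np.ndarray, family: str, params: Mapping,
            folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        est = _make_estimator(family, params, seed, proba=False)
        est.fit(X[train_idx], y[train_idx])
        preds[test_idx] = est.predict(X[test_idx])
    return metrics_report(confusion(y, preds)).mcc


def _tune(X: np.ndarray, y: np.ndarray, family: str, grid: Mapping[str, Sequence],
          folds: int, seed: int) -> dict:
    """Exhaustive grid search maximizing stratified-CV MCC (strict improvement,
    so earlier = smaller grid points win ties)."""
    points = _grid_points(grid)
    if len(points) == 1:
        return points[0]
    best_params, best_mcc = None, -np.inf
    for params in points:
        mcc = _cv_mcc(X, y, family, params, folds, seed)
        if mcc > best_mcc:
            best_params, best_mcc = params, mcc
    return best_params


def _hash_data(X: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy()).tobytes())
    h.update(np.asarray(y).tobytes())
    h.update("\x1f".join(map(str, X.columns)).encode())
    return h.hexdigest()[:16]


def grid_search_svm(
    X: pd.DataFrame,
    y: Sequence[int],
    c_exponents: Iterable[int] = range(-15, 11),
    g_exponents: Iterable[int] = range(-10, 11),
    folds: int = 10,
    seed: int = 0,
    refine: bool = False,
) -> tuple[tuple[float, float], TrainedModel]:
    """Grid-search an RBF-SVM over log2-spaced C and gamma and refit on all data.

    Ties in CV MCC resolve to the smallest C, then the smallest gamma.
    With ``refine`` a second pass searches the 2^±0.5 neighbourhood of the
    winning point at 2^0.25 resolution, for optima between integer exponents.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("two classes required")
    cs = [2.0**e for e in c_exponents]
    gs = [2.0**e for e in g_exponents]
    if not cs or not gs:
        raise ValueError("degenerate grid")
    Xv = X.to_numpy()
    if not np.isfinite(Xv).all():
        raise ValueError("features must be finite")
    params = _tune(Xv, y, "svm_rbf", {"C": cs, "gamma": gs}, folds, seed)
    if refine:
        deltas = [2.0 ** (0.25 * i) for i in range(-2, 3)]
        params = _tune(
            Xv, y, "svm_rbf",
            {"C": [params["C"] * d for d in deltas],
             "gamma": [params["gamma"] * d for d in deltas]},
            folds, seed,
        )
    est = _make_estimator("svm_rbf", params, seed)
    est.fit(Xv, y)
    model = TrainedModel(
        family="svm_rbf", estimator=est, params=params,
        feature_names=list(X.columns), seed=seed, data_hash=_hash_data(X, y),
    )
    return (params["C"], params["gamma"]), model


def _median_params(chosen: list[dict]) -> dict:
    out: dict = {}
    for key in chosen[0]:
        vals = [c[key] for c in chosen]
        if all(isinstance(v, (int, float, np.integer, np.floating)) for v in vals):
            med = statistics.median(vals)
            if all(isinstance(v, (int, np.integer)) for v in vals):
                med = int(round(med))
            out[key] = med
        else:
            out[key] = statistics.mode(vals)
    return out


def repeated_cv(
    X: pd.DataFrame,
    y: Sequence[int],
    spec: ModelSpec,
    repeats: int = 5,
    folds: int = 10,
    seed: int = 0,
    inner_folds: int = 3,
) -> CVResult:
    """Repeated stratified k-fold CV with per-fold nested hyperparameter tuning.

    Per repeat the data are re-partitioned into stratified folds; for each
    fold the grid is tuned by ``inner_folds``-fold CV on the training part
    only, the winning model is fit and the held-out fold scored. Metrics
    (including AUC over the pooled out-of-fold scores) are computed per
    repeat and averaged. A single-point grid skips the inner search.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2 or counts.min() < folds:
        raise ValueError(f"each class needs at least {folds} members for {folds}-fold CV")
    Xv = X.to_numpy()
    rows: list[dict] = []
    per_repeat: list[MetricsReport] = []
    chosen_params: list[dict] = []
    ids = list(X.index)
    for rep in range(repeats):
        rep_seed = (seed + 1009 * rep) % (2**31)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        oof_pred = np.empty_like(y)
        oof_score = np.empty(len(y), dtype=float)
        for fold, (train_idx, test_idx) in enumerate(skf.split(Xv, y)):
            params = _tune(Xv[train_idx], y[train_idx], spec.family, spec.grid,
                           inner_folds, rep_seed)
            chosen_params.append(params)
            est = _make_estimator(spec.family, params, rep_seed)
            est.fit(Xv[train_idx], y[train_idx])
            pos_col = list(est.classes_).index(1)
            score = est.predict_proba(Xv[test_idx])[:, pos_col]
            pred = est.predict(Xv[test_idx])
            oof_pred[test_idx] = pred
            oof_score[test_idx] = score
            for i, s, p in zip(test_idx, score, pred):
                rows.append({"id": ids[i], "label": int(y[i]), "repeat": rep,
                             "fold": fold, "score": float(s), "pred": int(p)})
        rep_report = metrics_report(confusion(y, oof_pred))
        rep_report.auc = roc_auc(oof_score, y)
        per_repeat.append(rep_report)
    mean = {
        k: float(np.mean([getattr(r, k) for r in per_repeat]))
        for k in ("sn", "sp", "acc", "mcc", "pt", "py", "auc")
    }
    report = MetricsReport(**mean, degenerate=any(r.degenerate for r in per_repeat))
    return CVResult(
        oof=pd.DataFrame(rows),
        per_repeat=per_repeat,
        report=report,
        chosen_params=chosen_params,
        median_params=_median_params(chosen_params),
        spec=spec,
        repeats=repeats,
        folds=folds,
        seed=seed,
    )


def fit_final(X: pd.DataFrame, y: Sequence[int], spec: ModelSpec,
              params: Mapping | None = None, seed: int = 0) -> TrainedModel:
    """Refit on all data (with the median CV hyperparameters, typically)."""
    y = np.asarray(y)
    params = dict(params) if params is not None else _grid_points(spec.grid)[0]
    est = _make_estimator(spec.family, params, seed)
    est.fit(X.to_numpy(), y)
    return TrainedModel(
        family=spec.family, estimator=est, params=params,
        feature_names=list(X.columns), seed=seed, data_hash=_hash_data(X, y),
    )


def predict(model: TrainedModel, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and positive-class probabilities for new feature rows.

    The columns of ``X`` must equal the model's feature contract exactly,
    order included; a mismatch raises :class:`ContractError` naming the
    missing/extra columns (or flags a pure ordering difference).
    """
    cols = list(X.columns)
    if cols != model.feature_names:
        missing = [c for c in model.feature_names if c not in set(cols)]
        extra = [c for c in cols if c not in set(model.feature_names)]
        if not missing and not extra:
            raise ContractError("feature columns are present but out of order")
        raise ContractError(f"feature contract mismatch: missing={missing[:5]}, "
                            f"extra={extra[:5]}")
    if len(X) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=float)
    est = model.estimator
    pos_col = list(est.classes_).index(1)
    scores = est.predict_proba(X.to_numpy())[:, pos_col]
    labels = est.predict(X.to_numpy())
    return np.asarray(labels, dtype=int), scores


def enumerate_experiment(
    blocks: Sequence[str] = ("MNC", "DNC", "TNC", "TeNC", "PNC", "DPCP", "TPCP"),
    fis_thresholds: Sequence[float] | None = None,
    hybrids: Mapping[str, tuple[str, ...]] | None = None,
    families: Sequence[str] = FAMILIES,
) -> list[dict]:
    """Enumerate the (family, feature-set) evaluation configurations.

    Defaults: 19 FIS-threshold sets + 7 single blocks + 7 hybrids = 33
    configurations per family, 132 over the four families.
    """
    if fis_thresholds is None:
        fis_thresholds = [0.0003 + 0.0001 * i for i in range(19)]
    if hybrids is None:
        hybrids = HYBRIDS
    configs: list[dict] = []
    for family in families:
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        for t in fis_thresholds:
            configs.append({"family": family, "feature_set": f"FIS>={t:.4f}",
                            "kind": "fis", "threshold": t})
        for b in blocks:
            configs.append({"family": family, "feature_set": b,
                            "kind": "block", "blocks": (b,)})
        for name, combo in hybrids.items():
            configs.append({"family": family, "feature_set": name,
                            "kind": "hybrid", "blocks": tuple(combo)})
    return configs
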
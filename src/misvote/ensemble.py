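"""Soft-voting ensemble of a random forest and a logistic regression.

The classifier couples two complementary learners: a tree ensemble that
captures non-linear interactions and is robust to unscaled inputs, and a
linear probabilistic model that extrapolates smoothly when strong features
(such as allele frequency) are missing or uninformative.  Their predicted
class probabilities are combined by a weighted average (soft voting):

    score = (w_t * p_tree + w_l * p_linear) / (w_t + w_l)

and a variant is called deleterious when its score strictly exceeds the
decision threshold (default 0.5; a score exactly at the threshold is
classified benign).

Feature selection is recursive feature elimination (RFE) run per learner:
iteratively fit, rank features (impurity importance for the forest,
absolute standardized coefficient for the regression), drop the lowest
ranked, and record the cross-validated AUC at each feature count.  Both
learners must keep the same number of features; each may keep its own set.

Hyper-parameters and voting weights are chosen by randomized search with
stratified cross-validation, selecting on mean held-out AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .datasets import LabeledDataset
from .features import FeatureMatrix

__all__ = [
    "SoftVotingModel",
    "RFETrace",
    "ModelFileError",
    "rfe_rank",
    "select_top_k",
    "fit_soft_voting",
    "predict_score",
    "classify",
    "feature_weight_report",
    "save_model",
    "load_model",
    "write_score_table",
    "DEFAULT_SEARCH_SPACE",
]

MODEL_FORMAT_VERSION = "misvote-model-1"

#: Randomized-search space over base-learner hyper-parameters and voting
#: weights.  Weights are drawn from a symmetric grid and normalized at
#: scoring time.
DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "rf__n_estimators": [100, 200, 300],
    "rf__max_depth": [None, 10, 20, 30],
    "rf__max_features": ["sqrt", "log2"],
    "rf__min_samples_leaf": [1, 2, 4],
    "lr__C": [0.01, 0.1, 1.0, 10.0],
    "w_tree": [0.25, 0.5, 0.75, 1.0],
    "w_linear": [0.25, 0.5, 0.75, 1.0],
}


class ModelFileError(RuntimeError):
    """A model file is corrupt or was written by an incompatible version."""


@dataclass
class RFETrace:
    """Elimination order and cross-validated performance curve of one RFE run.

    ``elimination_order`` lists every feature in removal order; the final
    element is the last survivor.  ``performance_curve`` holds
    ``(n_features_remaining, cv_auc)`` pairs, one per elimination state
    from the full set down to a single feature.
    """

    elimination_order: list[str]
    performance_curve: list[tuple[int, float]]
    learner_kind: str = "tree"


@dataclass
class SoftVotingModel:
    """Fitted two-learner soft-voting classifier."""

    tree: object
    linear: object
    scaler: object | None
    features_tree: list[str]
    features_linear: list[str]
    weights: tuple[float, float]
    threshold: float = 0.5
    train_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w_t, w_l = self.weights
        if w_t < 0 or w_l < 0 or (w_t == 0 and w_l == 0):
            raise ValueError(f"weights must be nonnegative, not both zero: {self.weights}")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1): {self.threshold}")
        if len(self.features_tree) != len(self.features_linear):
            raise ValueError(
                "soft voting requires both learners to use the same number of "
                f"features ({len(self.features_tree)} vs {len(self.features_linear)})"
            )


def _make_tree(params: Mapping, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params.get("rf__n_estimators", 200),
        max_depth=params.get("rf__max_depth"),
        max_features=params.get("rf__max_features", "sqrt"),
        min_samples_leaf=params.get("rf__min_samples_leaf", 1),
        random_state=seed,
        n_jobs=1,
    )


def _make_linear(params: Mapping, seed: int) -> LogisticRegression:
    return LogisticRegression(
        C=params.get("lr__C", 1.0), max_iter=2000, random_state=seed
    )


def _check_training_data(data: LabeledDataset, feature_names: Sequence[str]) -> np.ndarray:
    X = data.matrix.column_values(feature_names)
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite feature values")
    return X


def _cv_auc(estimator_factory, X, y, cv_folds: int, seed: int, standardize: bool) -> float:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        Xtr, Xte = X[tr], X[te]
        if standardize:
            sc = StandardScaler().fit(Xtr)
            Xtr, Xte = sc.transform(Xtr), sc.transform(Xte)
        est = estimator_factory()
        est.fit(Xtr, y[tr])
        aucs.append(roc_auc_score(y[te], est.predict_proba(Xte)[:, 1]))
    return float(np.mean(aucs))


def _rank_features(learner_kind: str, X, y, seed: int) -> np.ndarray:
    """Per-feature importance, higher = more important."""
    if learner_kind == "tree":
        est = _make_tree({"rf__n_estimators": 100}, seed)
        est.fit(X, y)
        return est.feature_importances_
    if learner_kind == "linear":
        sc = StandardScaler().fit(X)
        est = _make_linear({}, seed)
        est.fit(sc.transform(X), y)
        return np.abs(est.coef_[0])
    raise ValueError(f"unknown learner kind {learner_kind!r}")


def default_rfe_step(n_remaining: int) -> int:
    """Coarse-to-fine schedule: 7 features per round above 150, then 1."""
    return 7 if n_remaining > 150 else 1


def rfe_rank(
    data: LabeledDataset,
    learner_kind: str = "tree",
    step: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> RFETrace:
    """Recursive feature elimination from all features down to one.

    At each round the learner is refit on the surviving features, the
    cross-validated AUC at the current feature count is recorded, and the
    ``step`` lowest-ranked features are removed (least important first in
    ``elimination_order``).  ``step=None`` uses :func:`default_rfe_step`.
    """
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("RFE requires both classes present in the data")
    names = list(data.matrix.manifest.names)
    if len(names) < 2:
        raise ValueError("RFE requires at least 2 features")
    standardize = learner_kind == "linear"

    def factory():
        if learner_kind == "tree":
            return _make_tree({"rf__n_estimators": 100}, seed)
        return _make_linear({}, seed)

    remaining = list(names)
    order: list[str] = []
    curve: list[tuple[int, float]] = []
    name_to_col = {n: i for i, n in enumerate(names)}
    full_X = _check_training_data(data, names)
    while True:
        cols = [name_to_col[n] for n in remaining]
        X = full_X[:, cols]
        curve.append((len(remaining), _cv_auc(factory, X, y, cv_folds, seed, standardize)))
        if len(remaining) == 1:
            break
        k = step if step is not None else default_rfe_step(len(remaining))
        k = min(k, len(remaining) - 1)
        importance = _rank_features(learner_kind, X, y, seed)
        drop_idx = np.argsort(importance, kind="stable")[:k]
        dropped = [remaining[i] for i in sorted(drop_idx, key=lambda i: importance[i])]
        for d in dropped:
            order.append(d)
            remaining.remove(d)
    order.extend(remaining)  # the last survivor, eliminated never
    return RFETrace(order, curve, learner_kind)


def select_top_k(trace: RFETrace, k: int) -> list[str]:
    """The ``k`` features that survived elimination longest, longest first."""
    total = len(trace.elimination_order)
    if not 1 <= k <= total:
        raise ValueError(f"k must be in [1, {total}], got {k}")
    return list(reversed(trace.elimination_order[-k:]))


def fit_soft_voting(
    data: LabeledDataset,
    features_tree: Sequence[str] | None = None,
    features_linear: Sequence[str] | None = None,
    search_space: Mapping[str, list] | None = None,
    n_iter: int = 20,
    cv_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> SoftVotingModel:
    """Train the ensemble with randomized hyper-parameter search.

    ``n_iter`` candidate configurations (base-learner hyper-parameters plus
    voting weights) are sampled from ``search_space`` and scored by mean
    stratified cross-validated AUC of the combined soft vote; the best is
    refit on the full training data.  The standardizer for the linear
    learner is fit on training folds only during search, and on the full
    training set for the final refit.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    names = data.matrix.manifest.names
    features_tree = list(features_tree) if features_tree is not None else list(names)
    features_linear = list(features_linear) if features_linear is not None else list(names)
    if len(features_tree) != len(features_linear):
        raise ValueError(
            "both learners must receive the same number of features "
            f"({len(features_tree)} vs {len(features_linear)})"
        )
    space = dict(DEFAULT_SEARCH_SPACE)
    if search_space:
        space.update(search_space)
    y = data.labels
    Xt = _check_training_data(data, features_tree)
    Xl = _check_training_data(data, features_linear)

    metadata: dict = {
        "seed": seed,
        "n_iter": n_iter,
        "cv_folds": cv_folds,
        "n_train": len(data),
        "warnings": [],
    }
    n_pos, n_neg = data.n_positive, data.n_negative
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")
    ratio = max(n_pos, n_neg) / min(n_pos, n_neg)
    if ratio > 10:
        metadata["warnings"].append(
            f"class imbalance {ratio:.1f}:1 exceeds 10:1; "
            "probabilities may be poorly calibrated"
        )

    rng = np.random.default_rng(seed)
    keys = sorted(space)
    candidates = []
    for _ in range(n_iter):
        candidates.append({k: space[k][rng.integers(len(space[k]))] for k in keys})

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(Xt, y))
    best_score, best_params = -np.inf, None
    history = []
    for params in candidates:
        w_t, w_l = params["w_tree"], params["w_linear"]
        fold_aucs = []
        for tr, te in folds:
            tree = _make_tree(params, seed).fit(Xt[tr], y[tr])
            sc = StandardScaler().fit(Xl[tr])
            lin = _make_linear(params, seed).fit(sc.transform(Xl[tr]), y[tr])
            p = (
                w_t * tree.predict_proba(Xt[te])[:, 1]
                + w_l * lin.predict_proba(sc.transform(Xl[te]))[:, 1]
            ) / (w_t + w_l)
            fold_aucs.append(roc_auc_score(y[te], p))
        mean_auc = float(np.mean(fold_aucs))
        history.append({"params": params, "cv_auc": mean_auc})
        if mean_auc > best_score:
            best_score, best_params = mean_auc, params

    tree = _make_tree(best_params, seed).fit(Xt, y)
    scaler = StandardScaler().fit(Xl)
    linear = _make_linear(best_params, seed).fit(scaler.transform(Xl), y)
    metadata.update(
        {"best_params": best_params, "best_cv_auc": best_score, "search_history": history}
    )
    return SoftVotingModel(
        tree=tree,
        linear=linear,
        scaler=scaler,
        features_tree=features_tree,
        features_linear=features_linear,
        weights=(float(best_params["w_tree"]), float(best_params["w_linear"])),
        threshold=threshold,
        train_metadata=metadata,
    )


def _feature_block(matrix: FeatureMatrix, feature_names: Sequence[str]) -> np.ndarray:
    missing = [n for n in feature_names if n not in matrix.manifest.names]
    if missing:
        raise KeyError(f"matrix lacks model features: {missing}")
    idx = [matrix.manifest.names.index(n) for n in feature_names]
    cov = matrix.coverage[:, idx]
    if not cov.all():
        bad = sorted({feature_names[j] for j in np.unique(np.where(~cov)[1])})
        raise ValueError(
            f"uncovered feature values for {bad}; apply an imputation policy first"
        )
    return matrix.values[:, idx]


def predict_score(model: SoftVotingModel, matrix: FeatureMatrix) -> np.ndarray:
    """Per-variant deleteriousness score: the normalized weighted average of
    the two learners' positive-class probabilities, in [0, 1]."""
    if len(matrix) == 0:
        return np.zeros(0)
    Xt = _feature_block(matrix, model.features_tree)
    Xl = _feature_block(matrix, model.features_linear)
    p_tree = model.tree.predict_proba(Xt)[:, 1]
    if model.scaler is not None:
        Xl = model.scaler.transform(Xl)
    p_lin = model.linear.predict_proba(Xl)[:, 1]
    w_t, w_l = model.weights
    return (w_t * p_tree + w_l * p_lin) / (w_t + w_l)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 (deleterious) iff score strictly exceeds the threshold.

    A score exactly at the threshold is classified benign — the
    conservative choice for clinical shortlists.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return (scores > threshold).astype(int)


def feature_weight_report(model: SoftVotingModel) -> dict[str, dict[str, float]]:
    """Per-learner relative feature weights, normalized to sum to 100 %.

    Tree weights are impurity-based importances; linear weights are
    absolute coefficients on standardized inputs.
    """
    tree_raw = np.asarray(model.tree.feature_importances_, dtype=float)
    lin_raw = np.abs(np.asarray(model.linear.coef_[0], dtype=float))

    def _norm(raw: np.ndarray, names: Sequence[str]) -> dict[str, float]:
        total = raw.sum()
        if total == 0:
            pct = np.full(len(raw), 100.0 / len(raw))
        else:
            pct = 100.0 * raw / total
        return {n: float(p) for n, p in zip(names, pct)}

    return {
        "tree": _norm(tree_raw, model.features_tree),
        "linear": _norm(lin_raw, model.features_linear),
    }


def save_model(model: SoftVotingModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "tree": model.tree,
        "linear": model.linear,
        "scaler": model.scaler,
        "features_tree": model.features_tree,
        "features_linear": model.features_linear,
        "weights": model.weights,
        "threshold": model.threshold,
        "train_metadata": model.train_metadata,
    }
    joblib.dump(payload, path)


def load_model(path) -> SoftVotingModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt/truncated archives raise many types
        raise ModelFileError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFileError(f"{path} is not a model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFileError(
            f"model format {payload['format_version']!r} incompatible with "
            f"{MODEL_FORMAT_VERSION!r}"
        )
    return SoftVotingModel(
        tree=payload["tree"],
        linear=payload["linear"],
        scaler=payload["scaler"],
        features_tree=payload["features_tree"],
        features_linear=payload["features_linear"],
        weights=tuple(payload["weights"]),
        threshold=payload["threshold"],
        train_metadata=payload["train_metadata"],
    )


def write_score_table(model: SoftVotingModel, matrix: FeatureMatrix, scores: np.ndarray, path) -> None:
    """Write the precomputed-score layout: key columns, score, class."""
    classes = classify(scores, model.threshold)
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tscore\tclass\n")
        for v, s, c in zip(matrix.variants, scores, classes):
            label = "deleterious" if c else "benign"
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{s:.6f}\t{label}\n")
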
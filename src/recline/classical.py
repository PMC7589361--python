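"""Bagged decision-tree ensemble with majority voting, feature importance,
and the two linear baselines operating on per-axis episode means.

Each tree is fit on a bootstrap resample of the meta-feature matrix using a
random feature subset (default size round(sqrt(48)) = 7).  Trees are grown as
multi-output regressors on one-hot class indicators so that split quality is
variance reduction — i.e. mean-squared-error decrease — which keeps the
importance definition (summed MSE change per split feature, divided by the
tree's branch-node count, averaged over trees) well defined for
classification.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeRegressor

from recline.data import DEFAULT_LABELS, Episode
from recline.errors import ValidationError
from recline.features import FEATURE_NAMES, N_FEATURES

__all__ = [
    "BaselineModel",
    "EnsembleModel",
    "ImportanceReport",
    "episode_axis_means",
    "feature_importance",
    "load_ensemble",
    "predict_baseline",
    "predict_ensemble",
    "save_ensemble",
    "train_baseline",
    "train_ensemble",
]


@dataclass
class _TreeRecord:
    bootstrap_indices: np.ndarray
    feature_indices: np.ndarray
    tree: DecisionTreeRegressor


@dataclass
class EnsembleModel:
    n_trees: int
    label_vocabulary: tuple[str, ...]
    seed: int
    max_features: int
    trees: list[_TreeRecord] = field(default_factory=list)

    @property
    def is_trained(self) -> bool:
        return len(self.trees) == self.n_trees and self.n_trees > 0


@dataclass
class ImportanceReport:
    """Per-feature importance scores (length 48) and the descending ranking."""

    scores: np.ndarray
    feature_names: tuple[str, ...] = tuple(FEATURE_NAMES)

    @property
    def ranking(self) -> np.ndarray:
        # stable sort so equal scores rank in feature order
        return np.argsort(-self.scores, kind="stable")

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        return [
            (self.feature_names[i], float(self.scores[i]))
            for i in self.ranking[:k]
        ]


def _one_hot(labels: Sequence[str], vocab: tuple[str, ...]) -> np.ndarray:
    index = {lab: j for j, lab in enumerate(vocab)}
    try:
        cols = np.array([index[lab] for lab in labels])
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} not in vocabulary {vocab}")
    out = np.zeros((len(labels), len(vocab)))
    out[np.arange(len(labels)), cols] = 1.0
    return out


def train_ensemble(
    features: np.ndarray,
    labels: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
    *,
    label_vocabulary: Sequence[str] = DEFAULT_LABELS,
    max_features: Optional[int] = None,
    max_depth: Optional[int] = None,
    min_samples_leaf: int = 1,
    bootstrap: bool = True,
) -> EnsembleModel:
    """Fit the bagged tree ensemble on meta-feature vectors.

    ``bootstrap=False`` fits every tree on the full sample (useful for
    hand-checkable single-tree oracles); the default is standard bagging
    with resample size equal to the training-set size.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D matrix")
    n, p = X.shape
    if n != len(labels):
        raise ValidationError("features and labels length mismatch")
    if len(set(labels)) < 2:
        raise ValidationError("training requires at least 2 distinct labels")
    vocab = tuple(label_vocabulary)
    unknown = set(labels) - set(vocab)
    if unknown:
        raise ValidationError(f"labels {sorted(unknown)} not in vocabulary {vocab}")
    Y = _one_hot(labels, vocab)
    if max_features is None:
        max_features = int(round(np.sqrt(p)))
    max_features = min(max(1, max_features), p)

    rng = np.random.default_rng(seed)
    model = EnsembleModel(
        n_trees=n_trees,
        label_vocabulary=vocab,
        seed=seed,
        max_features=max_features,
    )
    for _ in range(n_trees):
        if bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        feats = np.sort(rng.choice(p, size=max_features, replace=False))
        tree = DecisionTreeRegressor(
            criterion="squared_error",
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx][:, feats], Y[idx])
        model.trees.append(_TreeRecord(idx, feats, tree))
    return model


def _tree_votes(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Vote counts of shape (n_samples, K)."""
    K = len(model.label_vocabulary)
    votes = np.zeros((X.shape[0], K), dtype=int)
    for rec in model.trees:
        pred = rec.tree.predict(X[:, rec.feature_indices])
        pred = np.atleast_2d(pred)
        winners = np.argmax(pred, axis=1)  # first index wins ties
        votes[np.arange(X.shape[0]), winners] += 1
    return votes


def predict_ensemble(
    model: EnsembleModel, features: np.ndarray
) -> "str | list[str]":
    """Majority vote over trees; ties broken by label-vocabulary order.

    Accepts one feature vector (returns one label) or a matrix (returns a
    list of labels).
    """
    if not model.is_trained:
        raise ValidationError("ensemble model is not trained")
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    votes = _tree_votes(model, X)
    winners = np.argmax(votes, axis=1)  # argmax → earliest vocab label on ties
    labels = [model.label_vocabulary[w] for w in winners]
    return labels[0] if single else labels


def feature_importance(model: EnsembleModel) -> ImportanceReport:
    """Importance per feature: per tree, sum each split's MSE decrease for
    its split feature, divide by the tree's branch-node count, then average
    the per-tree vectors across the ensemble."""
    if not model.is_trained:
        raise ValidationError("ensemble model is not trained")
    p = N_FEATURES
    total = np.zeros(p)
    for rec in model.trees:
        t = rec.tree.tree_
        per_tree = np.zeros(p)
        branch_nodes = 0
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:
                continue
            branch_nodes += 1
            delta = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            per_tree[rec.feature_indices[t.feature[node]]] += delta
        if branch_nodes:
            per_tree /= branch_nodes
        total += per_tree
    return ImportanceReport(scores=total / model.n_trees)


def save_ensemble(model: EnsembleModel, path: "str | Path") -> Path:
    """Persist the ensemble as a directory: JSON metadata + pickled trees."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "kind": "ensemble",
        "n_trees": model.n_trees,
        "label_vocabulary": list(model.label_vocabulary),
        "seed": model.seed,
        "max_features": model.max_features,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    with open(path / "trees.pkl", "wb") as fh:
        pickle.dump(model.trees, fh)
    return path


def load_ensemble(path: "str | Path") -> EnsembleModel:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    if meta.get("kind") != "ensemble" or meta.get("format_version") != 1:
        raise ValidationError(f"{path} is not a version-1 ensemble archive")
    with open(path / "trees.pkl", "rb") as fh:
        trees = pickle.load(fh)
    return EnsembleModel(
        n_trees=meta["n_trees"],
        label_vocabulary=tuple(meta["label_vocabulary"]),
        seed=meta["seed"],
        max_features=meta["max_features"],
        trees=trees,
    )


# ---------------------------------------------------------------------------
# Linear baselines on per-axis episode means
# ---------------------------------------------------------------------------

BaselineKind = Literal["lda_means", "svm_linear_means"]


@dataclass
class BaselineModel:
    kind: BaselineKind
    estimator: object
    label_vocabulary: tuple[str, ...]


def episode_axis_means(episodes: Sequence[Episode]) -> np.ndarray:
    """The 3-vector of per-axis signal means for each episode."""
    return np.stack([ep.samples.mean(axis=0) for ep in episodes])


def train_baseline(
    kind: BaselineKind,
    episodes: Sequence[Episode],
    labels: Sequence[str],
    *,
    label_vocabulary: Sequence[str] = DEFAULT_LABELS,
    lda_shrinkage: Optional[float] = None,
) -> BaselineModel:
    """Fit one of the linear baselines on per-axis episode means."""
    if len(set(labels)) < 2:
        raise ValidationError("baseline training requires >= 2 classes")
    X = episode_axis_means(episodes)
    y = np.asarray(labels)
    if kind == "lda_means":
        if lda_shrinkage is None:
            est = LinearDiscriminantAnalysis()
        else:
            est = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=lda_shrinkage
            )
        try:
            est.fit(X, y)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "LDA failed on singular within-class covariance; retry with "
                "lda_shrinkage (e.g. 0.1) to regularize"
            ) from exc
    elif kind == "svm_linear_means":
        est = SVC(kernel="linear")
        est.fit(X, y)
    else:
        raise ValidationError(f"unknown baseline kind {kind!r}")
    return BaselineModel(kind, est, tuple(label_vocabulary))


def predict_baseline(
    model: BaselineModel, episodes: Sequence[Episode]
) -> list[str]:
    X = episode_axis_means(episodes)
    return [str(lab) for lab in model.estimator.predict(X)]
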
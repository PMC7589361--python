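"""Leave-one-subject-out evaluation harness and metric formulas.

The metric definitions follow the formulas used for reporting:

* ``accuracy`` is the *macro* average of the per-class one-vs-rest
  accuracies (TP_i + TN_i) / (TP_i + TN_i + FP_i + FN_i); the conventional
  pooled accuracy is exposed separately as :func:`pooled_accuracy`.
* ``precision`` / ``recall`` are macro averages; a class with a zero
  denominator contributes 0 with a warning.
* ``f1`` is the harmonic mean of the macro precision and macro recall.
* ``balanced_accuracy`` = (sum_i TP_i/P_i + sum_i TN_i/N_i) / (2 l).
* ``cov`` is the coefficient of variation: sample standard deviation of a
  metric over folds divided by its mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from recline import adalstm as _adalstm
from recline import classical as _classical
from recline import features as _features
from recline.data import BodySite, Dataset, normalize_episode
from recline.errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "FoldResult",
    "MetricSummary",
    "MODEL_SPECS",
    "accuracy",
    "balanced_accuracy",
    "cov",
    "f1",
    "kruskal_compare",
    "loso_splits",
    "pooled_accuracy",
    "precision_recall",
    "run_loso",
]

MODEL_SPECS = ("ensemble", "adalstm", "lda", "svm", "lstm_fixed")


@dataclass(frozen=True)
class ConfusionMatrix:
    """l x l integer counts; rows are true labels, columns predictions."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        l = len(self.labels)
        if arr.shape != (l, l):
            raise ValidationError(
                f"confusion matrix shape {arr.shape} != ({l}, {l})"
            )
        if (arr < 0).any():
            raise ValidationError("confusion matrix counts must be >= 0")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        labels: Sequence[str],
    ) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        arr = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            arr[index[t], index[p]] += 1
        return cls(arr, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> pd.DataFrame:
        """TP/FP/FN/TN/P/N per class."""
        cm = self.counts
        tp = np.diag(cm)
        fn = cm.sum(axis=1) - tp
        fp = cm.sum(axis=0) - tp
        tn = self.total - tp - fn - fp
        return pd.DataFrame(
            {"TP": tp, "FP": fp, "FN": fn, "TN": tn, "P": tp + fn, "N": tn + fp},
            index=list(self.labels),
        )

    def restrict(self, labels: Sequence[str]) -> "ConfusionMatrix":
        """Sub-matrix over the given labels (rows and columns)."""
        idx = [self.labels.index(lab) for lab in labels]
        return ConfusionMatrix(self.counts[np.ix_(idx, idx)], tuple(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.labels), columns=list(self.labels)
        )


def _check_nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValidationError("confusion matrix is empty")


def accuracy(cm: ConfusionMatrix) -> float:
    """Mean over classes of the one-vs-rest accuracies."""
    _check_nonempty(cm)
    t = cm.per_class()
    per = (t.TP + t.TN) / (t.TP + t.TN + t.FP + t.FN)
    return float(per.mean())


def pooled_accuracy(cm: ConfusionMatrix) -> float:
    """Conventional accuracy: trace / total."""
    _check_nonempty(cm)
    return float(np.trace(cm.counts) / cm.total)


def precision_recall(cm: ConfusionMatrix) -> tuple[float, float]:
    """Macro precision and recall; zero-denominator classes contribute 0."""
    _check_nonempty(cm)
    t = cm.per_class()
    prec_terms, rec_terms = [], []
    for lab, row in t.iterrows():
        pd_ = row.TP + row.FP
        if pd_ == 0:
            warnings.warn(
                f"class {lab!r} never predicted; precision term set to 0",
                RuntimeWarning,
            )
            prec_terms.append(0.0)
        else:
            prec_terms.append(row.TP / pd_)
        rd = row.TP + row.FN
        if rd == 0:
            warnings.warn(
                f"class {lab!r} has no positives; recall term set to 0",
                RuntimeWarning,
            )
            rec_terms.append(0.0)
        else:
            rec_terms.append(row.TP / rd)
    return float(np.mean(prec_terms)), float(np.mean(rec_terms))


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of macro precision and macro recall."""
    prec, rec = precision_recall(cm)
    if prec + rec == 0:
        warnings.warn("precision and recall both 0; F1 set to 0", RuntimeWarning)
        return 0.0
    return 2.0 * prec * rec / (prec + rec)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """(sum_i TP_i/P_i + sum_i TN_i/N_i) / (2 l)."""
    _check_nonempty(cm)
    t = cm.per_class()
    for lab, row in t.iterrows():
        if row.P == 0:
            raise ValidationError(
                f"class {lab!r} has zero positive samples; balanced accuracy "
                "is undefined"
            )
        if row.N == 0:
            raise ValidationError(
                f"class {lab!r} has zero negative samples; balanced accuracy "
                "is undefined"
            )
    l = len(cm.labels)
    return float(((t.TP / t.P).sum() + (t.TN / t.N).sum()) / (2 * l))


def cov(metric_values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (N-1) divided by the mean."""
    values = np.asarray(metric_values, dtype=float)
    if values.size < 2:
        raise ValidationError("CoV requires at least 2 values")
    mu = values.mean()
    if mu == 0:
        raise ValidationError("CoV undefined: mean is 0")
    return float(values.std(ddof=1) / mu)


def kruskal_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Kruskal-Wallis rank-test p-value for two groups."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([np.asarray(group_a), np.asarray(group_b)])
    if np.all(pooled == pooled[0]):
        raise ValidationError(
            "degenerate Kruskal statistic: all values identical"
        )
    try:
        return float(stats.kruskal(list(group_a), list(group_b)).pvalue)
    except ValueError as exc:  # all values identical
        raise ValidationError(f"degenerate Kruskal statistic: {exc}") from exc


# ---------------------------------------------------------------------------
# LOSO harness
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    subject_id: str
    cm: ConfusionMatrix
    metrics: dict[str, float]


@dataclass
class MetricSummary:
    """Mean, SD and CoV per metric over LOSO folds."""

    per_metric: pd.DataFrame  # index metric, columns mean/sd/cov

    def to_dict(self) -> dict:
        return {
            metric: {k: float(v) for k, v in row.items()}
            for metric, row in self.per_metric.iterrows()
        }


def loso_splits(dataset: Dataset) -> list[tuple[list[str], str]]:
    """One fold per subject: (training subjects, held-out subject)."""
    subjects = sorted(dataset.subjects)
    if len(subjects) < 2:
        raise ValidationError(
            "LOSO requires at least 2 subjects; got "
            f"{len(subjects)} ({subjects})"
        )
    return [([s for s in subjects if s != t], t) for t in subjects]


class _EnsembleAdapter:
    def __init__(self, seed: int, params: dict):
        self.seed = seed
        self.params = params

    def fit(self, episodes, labels, vocab):
        w = _features.training_window_length(list(episodes))
        self.spec = _features.WindowingSpec(w)
        X = np.stack(
            [_features.episode_meta_features(e, self.spec) for e in episodes]
        )
        self.model = _classical.train_ensemble(
            X,
            labels,
            n_trees=self.params.get("n_trees", 100),
            seed=self.seed,
            label_vocabulary=vocab,
            max_features=self.params.get("max_features"),
        )

    def predict(self, episodes):
        X = np.stack(
            [_features.episode_meta_features(e, self.spec) for e in episodes]
        )
        return _classical.predict_ensemble(self.model, X)


class _BaselineAdapter:
    def __init__(self, kind: str, params: dict):
        self.kind = kind
        self.params = params

    def fit(self, episodes, labels, vocab):
        self.model = _classical.train_baseline(
            self.kind,
            episodes,
            labels,
            label_vocabulary=vocab,
            lda_shrinkage=self.params.get("lda_shrinkage"),
        )

    def predict(self, episodes):
        return _classical.predict_baseline(self.model, episodes)


class _AdaLSTMAdapter:
    def __init__(self, seed: int, params: dict, *, constant_lr: bool):
        self.seed = seed
        self.params = dict(params)
        self.constant_lr = constant_lr

    def fit(self, episodes, labels, vocab):
        cfg = _adalstm.AdaLSTMConfig(
            n_classes=len(vocab),
            seed=self.seed,
            lr_schedule="constant" if self.constant_lr else "piecewise",
            **{
                k: v
                for k, v in self.params.items()
                if k in _adalstm.AdaLSTMConfig.__dataclass_fields__
                and k not in ("n_classes", "seed", "lr_schedule")
            },
        )
        self.model = _adalstm.build_model(cfg, vocab)
        _adalstm.train(self.model, list(zip(episodes, labels)))

    def predict(self, episodes):
        return _adalstm.predict(self.model, episodes)


def _make_adapter(model_spec, seed: int, params: Optional[dict]):
    params = params or {}
    if not isinstance(model_spec, str):
        return model_spec  # custom adapter with fit/predict
    if model_spec == "ensemble":
        return _EnsembleAdapter(seed, params)
    if model_spec == "lda":
        return _BaselineAdapter("lda_means", params)
    if model_spec == "svm":
        return _BaselineAdapter("svm_linear_means", params)
    if model_spec == "adalstm":
        return _AdaLSTMAdapter(seed, params, constant_lr=False)
    if model_spec == "lstm_fixed":
        return _AdaLSTMAdapter(seed, params, constant_lr=True)
    raise ValidationError(
        f"unknown model_spec {model_spec!r}; expected one of {MODEL_SPECS}"
    )


def _fold_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    present = [
        lab for i, lab in enumerate(cm.labels) if cm.counts[i].sum() > 0
    ]
    eff = cm.restrict(present) if len(present) < len(cm.labels) else cm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prec, rec = precision_recall(eff)
        return {
            "accuracy": accuracy(eff),
            "pooled_accuracy": pooled_accuracy(eff),
            "precision": prec,
            "recall": rec,
            "f1": f1(eff),
            "balanced_accuracy": balanced_accuracy(eff)
            if len(present) > 1
            else float("nan"),
        }


def run_loso(
    dataset: Dataset,
    model_spec,
    site: "BodySite | str | None" = None,
    seed: int = 0,
    *,
    model_params: Optional[dict] = None,
    normalize: bool = True,
    progress: Optional[Callable[[str], None]] = None,
) -> tuple[list[FoldResult], MetricSummary]:
    """Leave-one-subject-out evaluation of one model at one body site.

    ``model_spec`` is one of :data:`MODEL_SPECS` or any object with
    ``fit(episodes, labels, vocab)`` and ``predict(episodes)`` methods.
    The feature window length is recomputed inside each fold from the
    fold's training episodes only.  Deterministic for a fixed seed.
    """
    ds = dataset.filter(site=site) if site is not None else dataset
    if not ds.episodes:
        raise ValidationError(f"no episodes at site {site!r}")
    if normalize:
        ds = Dataset(
            ds.name,
            [normalize_episode(e) for e in ds.episodes],
            ds.label_vocabulary,
        )
    vocab = ds.label_vocabulary
    folds = loso_splits(ds)
    results: list[FoldResult] = []
    seed_seq = np.random.SeedSequence(seed)
    fold_seeds = seed_seq.generate_state(len(folds))
    for (train_subjects, test_subject), fold_seed in zip(folds, fold_seeds):
        train_eps = [e for e in ds.episodes if e.subject_id != test_subject]
        test_eps = [e for e in ds.episodes if e.subject_id == test_subject]
        train_labels = [e.posture for e in train_eps]
        if len(set(train_labels)) < 2:
            warnings.warn(
                f"fold {test_subject}: single-class training split; skipped",
                RuntimeWarning,
            )
            continue
        if progress:
            progress(f"fold {test_subject}: train {len(train_eps)}, "
                     f"test {len(test_eps)}")
        adapter = _make_adapter(model_spec, int(fold_seed), model_params)
        adapter.fit(train_eps, train_labels, vocab)
        preds = adapter.predict(test_eps)
        cm = ConfusionMatrix.from_predictions(
            [e.posture for e in test_eps], list(preds), vocab
        )
        results.append(FoldResult(test_subject, cm, _fold_metrics(cm)))

    if not results:
        raise ValidationError("all LOSO folds were skipped")
    metric_names = results[0].metrics.keys()
    rows = {}
    for name in metric_names:
        values = np.array([r.metrics[name] for r in results])
        values = values[~np.isnan(values)]
        mu = float(values.mean()) if values.size else float("nan")
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        rows[name] = {
            "mean": mu,
            "sd": sd,
            "cov": sd / mu if mu else float("nan"),
        }
    summary = MetricSummary(pd.DataFrame(rows).T[["mean", "sd", "cov"]])
    return results, summary
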
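"""Pair dataset assembly, the classifier bank, evaluation metrics and ranking.

The labeled dataset pairs every fused (drug, target) embedding with the
corresponding binary interaction label; all non-interacting pairs are kept as
negatives (no subsampling).  Nine classifiers are supported, with default
hyperparameters fixed per feature scenario (pure knowledge-graph embeddings,
KGE drugs + protein-language-model targets, or local fingerprint/sequence
features).  Threshold metrics (precision, recall, accuracy, F1, Matthews
correlation) are computed from the confusion counts with the convention that
a zero denominator yields 0; ranking metrics are ROC AUC and area under the
precision-recall curve.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .fusion import InteractionMatrix, PairEmbedding

__all__ = [
    "CLASSIFIER_NAMES",
    "SCENARIOS",
    "ClassifierSpec",
    "EvalReport",
    "PairDataset",
    "build_pair_dataset",
    "make_classifier",
    "confusion_metrics",
    "curve_metrics",
    "crossvalidate",
    "relative_gap",
    "rank_novel",
]

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = (
    "rf",
    "dt",
    "mlp",
    "kneighbors",
    "bagging",
    "gradientboosting",
    "gaussiannb",
    "sgd",
    "etc",
)
SCENARIOS = ("kge", "kge-protbert", "local")


@dataclass
class PairDataset:
    """Fused pair embeddings X with binary labels y mirroring the interactions."""

    X: np.ndarray
    y: np.ndarray
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.pairs):
            raise ValueError("X, y and pairs must agree in length")


@dataclass
class ClassifierSpec:
    """A classifier-bank member: name plus scenario-resolved parameters."""

    name: str = "rf"
    scenario: str = "kge"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"classifier must be one of {CLASSIFIER_NAMES}, got {self.name!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")

    def build(self):
        return make_classifier(self.name, self.scenario, **self.params)


@dataclass
class EvalReport:
    """Threshold and ranking metrics plus raw confusion counts."""

    aupr: float = 0.0
    auc: float = 0.0
    acc: float = 0.0
    mcc: float = 0.0
    f1: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    tp: float = 0.0
    fp: float = 0.0
    tn: float = 0.0
    fn: float = 0.0


def make_classifier(name: str, scenario: str = "kge", **overrides):
    """Instantiate a bank classifier with its scenario's default parameters.

    Unstated tree counts default to 100; fixed random states keep every
    member deterministic.  ``overrides`` replace any default keyword.
    """
    if name not in CLASSIFIER_NAMES:
        raise ValueError(f"classifier must be one of {CLASSIFIER_NAMES}, got {name!r}")
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    wide = scenario != "kge"  # the two feature-rich scenarios share settings
    defaults: dict = {}
    if name == "rf":
        cls = RandomForestClassifier
        defaults = dict(
            n_estimators=100, criterion="gini", class_weight="balanced", random_state=1357
        )
    elif name == "dt":
        cls = DecisionTreeClassifier
        defaults = dict(random_state=1357)
    elif name == "mlp":
        cls = MLPClassifier
        defaults = dict(
            solver="lbfgs",
            alpha=1e-5,
            hidden_layer_sizes=(240, 96) if wide else (5, 2),
            random_state=1,
        )
    elif name == "kneighbors":
        cls = KNeighborsClassifier
        defaults = dict(n_neighbors=2 if wide else 7)
    elif name == "bagging":
        cls = BaggingClassifier
        if wide:
            defaults = dict(
                estimator=KNeighborsClassifier(n_neighbors=1),
                max_samples=1.0,
                max_features=1.0,
                random_state=1357,
            )
        else:
            defaults = dict(
                estimator=KNeighborsClassifier(),
                max_samples=0.5,
                max_features=0.5,
                random_state=1357,
            )
    elif name == "gradientboosting":
        cls = GradientBoostingClassifier
        defaults = dict(
            n_estimators=100, learning_rate=1.0, max_depth=2 if wide else 1, random_state=0
        )
    elif name == "gaussiannb":
        cls = GaussianNB
    elif name == "sgd":
        cls = SGDClassifier
        defaults = dict(
            loss="log_loss", penalty="l2", max_iter=2 if wide else 5, random_state=1357
        )
    else:  # etc
        cls = ExtraTreesClassifier
        defaults = dict(n_estimators=100, random_state=1357)
    defaults.update(overrides)
    return cls(**defaults)


def build_pair_dataset(
    pair_embeddings: list[PairEmbedding], mat_int: InteractionMatrix
) -> PairDataset:
    """Label every fused pair by its interaction-matrix entry."""
    needed = {(d, t) for d in mat_int.drug_ids for t in mat_int.target_ids}
    have = {(p.drug, p.target) for p in pair_embeddings}
    missing = needed - have
    if missing:
        raise ValueError(f"missing pair embedding for {sorted(missing)[0]} (+{len(missing) - 1} more)")
    X = np.stack([p.vector for p in pair_embeddings])
    y = np.array([mat_int.entry(p.drug, p.target) for p in pair_embeddings])
    return PairDataset(X, y, [(p.drug, p.target) for p in pair_embeddings])


def confusion_metrics(tp: float, fp: float, tn: float, fn: float) -> EvalReport:
    """Threshold metrics from confusion counts; zero denominators give 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("confusion counts must sum to a positive total")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    acc = (tn + tp) / total
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return EvalReport(
        acc=acc, mcc=mcc, f1=f1, precision=precision, recall=recall,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def curve_metrics(y_true: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """ROC AUC (probability of correct ranking, ties averaged) and AUPR."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("curve metrics need both classes present in y_true")
    auc = float(roc_auc_score(y_true, scores))
    aupr = float(average_precision_score(y_true, scores))
    return auc, aupr


def _predict_scores(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(1)
    return proba[:, pos_col]


def crossvalidate(
    dataset: PairDataset,
    spec: ClassifierSpec,
    folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation at the pair level, fold-averaged.

    Per fold the classifier is refit, interaction probabilities are predicted
    for the held-out pairs, and all metrics are computed; the report holds
    the fold means (confusion counts are per-fold means as well).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("both classes must be present in the dataset")
    if int(dataset.y.sum()) < folds or int((1 - dataset.y).sum()) < folds:
        raise ValueError(
            "a class has fewer members than folds, which would leave a fold "
            "with one class; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    estimator = spec.build()
    reports: list[EvalReport] = []
    for train_idx, test_idx in skf.split(dataset.X, dataset.y):
        model = clone(estimator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny max_iter members warn on purpose
            model.fit(dataset.X[train_idx], dataset.y[train_idx])
        y_test = dataset.y[test_idx]
        if len(np.unique(y_test)) < 2:
            raise ValueError("a fold contains one class only; use fewer folds")
        scores = _predict_scores(model, dataset.X[test_idx])
        y_hat = (scores >= 0.5).astype(int)
        tp = int(np.sum((y_hat == 1) & (y_test == 1)))
        fp = int(np.sum((y_hat == 1) & (y_test == 0)))
        tn = int(np.sum((y_hat == 0) & (y_test == 0)))
        fn = int(np.sum((y_hat == 0) & (y_test == 1)))
        rep = confusion_metrics(tp, fp, tn, fn)
        rep.auc, rep.aupr = curve_metrics(y_test, scores)
        reports.append(rep)
    out = EvalReport()
    for f in dc_fields(EvalReport):
        setattr(out, f.name, float(np.mean([getattr(r, f.name) for r in reports])))
    return out


def relative_gap(a: float, b: float) -> float:
    """Percentage gap ``100 * (a - b) / a`` to two decimals; requires a > 0."""
    if a <= 0:
        raise ValueError("relative_gap needs a positive reference value a")
    return round(100.0 * (a - b) / a, 2)


def rank_novel(model, dataset: PairDataset, k: int = 10) -> list[tuple[str, str, float]]:
    """Top-k candidate interactions among pairs not already known positive.

    Pairs are sorted by predicted interaction probability, descending, with
    ties broken by (drug id, target id).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = _predict_scores(model, dataset.X)
    candidates = [
        (pair[0], pair[1], float(s))
        for pair, s, label in zip(dataset.pairs, scores, dataset.y)
        if label == 0
    ]
    candidates.sort(key=lambda item: (-item[2], item[0], item[1]))
    if k > len(candidates):
        logger.warning("k=%d exceeds %d candidates; truncating", k, len(candidates))
    return candidates[:k]


def write_ranking(ranking: list[tuple[str, str, float]], path) -> None:
    """``rank<TAB>drug_id<TAB>target_id<TAB>probability`` per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rank, (d, t, p) in enumerate(ranking, start=1):
            fh.write(f"{rank}\t{d}\t{t}\t{p:.6f}\n")
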
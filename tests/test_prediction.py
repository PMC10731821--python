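"""Pair datasets, confusion/curve metrics, cross-validation and ranking."""

import itertools
import math
import warnings

import numpy as np
import pytest

from dtilink import (
    ClassifierSpec,
    InteractionMatrix,
    build_pair_dataset,
    confusion_metrics,
    crossvalidate,
    curve_metrics,
    make_classifier,
    rank_novel,
    relative_gap,
)
from dtilink.fusion import PairEmbedding
from dtilink.prediction import CLASSIFIER_NAMES, PairDataset


def _pairs_for(mat):
    rng = np.random.default_rng(0)
    return [
        PairEmbedding(d, t, rng.standard_normal(4))
        for d in mat.drug_ids
        for t in mat.target_ids
    ]


class TestBuildPairDataset:
    def test_labels_mirror_interactions(self):
        mat = InteractionMatrix(
            ["d0", "d1", "d2"], ["t0", "t1", "t2", "t3"],
            np.array([[1, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 1]]),
        )
        ds = build_pair_dataset(_pairs_for(mat), mat)
        assert len(ds.y) == 12
        assert ds.y.sum() == 5
        for (d, t), label in zip(ds.pairs, ds.y):
            assert label == mat.entry(d, t)

    def test_all_zero_matrix(self):
        mat = InteractionMatrix(["d0", "d1"], ["t0", "t1"], np.zeros((2, 2), dtype=int))
        ds = build_pair_dataset(_pairs_for(mat), mat)
        assert ds.y.sum() == 0

    def test_missing_pair_errors(self):
        mat = InteractionMatrix(["d0", "d1"], ["t0"], np.array([[1], [0]]))
        with pytest.raises(ValueError, match="missing pair"):
            build_pair_dataset(_pairs_for(mat)[:1], mat)


def _oracle_confusion(tp, fp, tn, fn):
    """Direct formula evaluation, independent of the implementation."""
    div = lambda num, den: num / den if den > 0 else 0.0
    precision = div(tp, tp + fp)
    recall = div(tp, tp + fn)
    acc = (tn + tp) / (tp + fp + tn + fn)
    f1 = div(2 * precision * recall, precision + recall)
    mcc = div(tp * tn - fp * fn, math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return precision, recall, acc, f1, mcc


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        rep = confusion_metrics(1, 0, 1, 0)
        assert (rep.precision, rep.recall, rep.acc, rep.f1, rep.mcc) == (1, 1, 1, 1, 1)

    def test_coin_flip_symmetry(self):
        rep = confusion_metrics(25, 25, 25, 25)
        assert rep.mcc == 0.0 and rep.acc == 0.5

    def test_hand_arithmetic(self):
        rep = confusion_metrics(50, 10, 30, 10)
        assert rep.precision == pytest.approx(50 / 60)
        assert rep.recall == pytest.approx(50 / 60)
        assert rep.acc == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(50 / 60)
        assert rep.mcc == pytest.approx(1400 / 2400)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)

    def test_exhaustive_against_oracle(self):
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            rep = confusion_metrics(tp, fp, tn, fn)
            precision, recall, acc, f1, mcc = _oracle_confusion(tp, fp, tn, fn)
            assert rep.precision == pytest.approx(precision)
            assert rep.recall == pytest.approx(recall)
            assert rep.acc == pytest.approx(acc)
            assert rep.f1 == pytest.approx(f1)
            assert rep.mcc == pytest.approx(mcc)


def _mann_whitney_auc(y, scores):
    pos = [s for s, label in zip(scores, y) if label == 1]
    neg = [s for s, label in zip(scores, y) if label == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestCurveMetrics:
    def test_perfect_and_inverted_ordering(self):
        y = np.array([1, 1, 0, 0])
        assert curve_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]))[0] == 1.0
        assert curve_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))[0] == 0.0

    def test_pairwise_count_example(self):
        y = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        auc, aupr = curve_metrics(y, scores)
        assert auc == pytest.approx(0.75)
        assert 0 <= aupr <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        auc, _ = curve_metrics(y, scores)
        assert auc == pytest.approx(_mann_whitney_auc(y, scores))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            curve_metrics(np.ones(4), np.arange(4.0))


class TestRelativeGap:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.968, 0.755, 22.00), (0.5, 0.5, 0.00), (0.996, 0.836, 16.06)]
    )
    def test_examples(self, a, b, expected):
        assert relative_gap(a, b) == expected

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            relative_gap(0.0, 0.3)


def _separable_dataset(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.standard_normal((n, 6)) + 3.0 * y[:, None]
    pairs = [(f"d{i}", f"t{i}") for i in range(n)]
    return PairDataset(X, y, pairs)


class TestCrossvalidate:
    def test_separable_signal_recovered(self):
        ds = _separable_dataset()
        rep = crossvalidate(ds, ClassifierSpec("rf"), folds=5, seed=0)
        assert rep.auc >= 0.95

    def test_shuffled_labels_null_auc(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = _separable_dataset(seed=seed)
            y = rng.permutation(ds.y)
            rep = crossvalidate(PairDataset(ds.X, y, ds.pairs), ClassifierSpec("dt"), 5, seed)
            aucs.append(rep.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_same_seed_identical_report(self):
        ds = _separable_dataset()
        a = crossvalidate(ds, ClassifierSpec("rf"), folds=4, seed=11)
        b = crossvalidate(ds, ClassifierSpec("rf"), folds=4, seed=11)
        assert a == b

    def test_class_smaller_than_folds_errors(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        y = np.array([1, 1] + [0] * 8)
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(PairDataset(X, y, [("d", str(i)) for i in range(10)]), ClassifierSpec("dt"), folds=3)

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_every_bank_member_fits_and_scores(self, name):
        ds = _separable_dataset(n=200, seed=2)
        model = make_classifier(name, "kge")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(ds.X, ds.y)
            proba = model.predict_proba(ds.X)
        assert proba.shape == (200, 2)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="rf"):
            make_classifier("xgboost")


class TestRankNovel:
    def _fit_model(self, ds):
        model = make_classifier("rf", "kge")
        model.fit(ds.X, ds.y)
        return model

    def test_known_positives_excluded_and_sorted(self):
        ds = _separable_dataset(n=60, seed=4)
        model = self._fit_model(ds)
        out = rank_novel(model, ds, k=10)
        positives = {p for p, label in zip(ds.pairs, ds.y) if label == 1}
        assert len(out) == 10
        assert all((d, t) not in positives for d, t, _ in out)
        probs = [p for _, _, p in out]
        assert probs == sorted(probs, reverse=True)

    def test_k_one_singleton(self):
        ds = _separable_dataset(n=30, seed=5)
        out = rank_novel(self._fit_model(ds), ds, k=1)
        assert len(out) == 1

    def test_oversized_k_truncates_with_warning(self, caplog):
        import logging

        ds = _separable_dataset(n=20, seed=6)
        n_negatives = int((ds.y == 0).sum())
        with caplog.at_level(logging.WARNING, logger="dtilink.prediction"):
            out = rank_novel(self._fit_model(ds), ds, k=n_negatives + 5)
        assert len(out) == n_negatives
        assert any("truncating" in r.message for r in caplog.records)
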
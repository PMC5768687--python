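"""Model selection, prediction contracts and confidence ranking."""

import numpy as np
import pandas as pd
import pytest

import camikit as ck
from camikit.classify import (
    DISCARD_CLASS,
    PhenotypePrediction,
    TrainingSet,
    predict_all,
    rank_and_pick,
    train_and_select,
)


def _gaussian_training(n_per_class=200, sep=6.0, seed=0, d=10):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_class, d))
    b = rng.normal(sep, 1.0, (n_per_class, d))
    X = np.vstack([a, b])
    y = np.array(["neg"] * n_per_class + ["pos"] * n_per_class)
    return TrainingSet(X, y, ("neg", "pos"))


class TestTrainAndSelect:
    def test_separable_classes_near_perfect_cv(self):
        model, report = train_and_select(_gaussian_training(), k=10, seed=0)
        assert report.cv_accuracy[report.chosen_algorithm] >= 0.99

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        train = _gaussian_training(seed=1)
        shuffled = TrainingSet(train.features,
                               rng.permutation(train.labels),
                               train.label_set)
        _, report = train_and_select(shuffled, k=10, seed=1)
        for acc in report.cv_accuracy.values():
            assert 0.4 <= acc <= 0.6

    def test_fold_count_boundary(self):
        # smallest legal configuration: k equals the thinnest class size
        train = _gaussian_training(n_per_class=6, seed=2)
        model, report = train_and_select(train, k=6, seed=2)
        assert set(report.cv_accuracy) == {
            "random_forest", "logistic_regression", "knn", "svm"}

    def test_thin_class_rejected_with_guidance(self):
        train = _gaussian_training(n_per_class=5, seed=3)
        with pytest.raises(ValueError, match="reduce k"):
            train_and_select(train, k=10, seed=3)

    def test_deterministic_given_seed(self):
        train = _gaussian_training(n_per_class=30, sep=1.0, seed=4)
        _, r1 = train_and_select(train, k=5, seed=7)
        _, r2 = train_and_select(train, k=5, seed=7)
        assert r1.cv_accuracy == r2.cv_accuracy
        assert r1.chosen_algorithm == r2.chosen_algorithm


class TestPredictAll:
    def test_training_exemplar_recovered_with_confidence(self):
        train = _gaussian_training()
        model, _ = train_and_select(train, k=5, seed=0)
        preds = predict_all(model, train.features[:5], list(range(5)))
        for p in preds:
            assert p.predicted_class == "neg"
            assert p.confidence > 0.9

    def test_conservation_and_score_validity(self):
        train = _gaussian_training(n_per_class=50)
        model, _ = train_and_select(train, k=5, seed=0)
        X = train.features
        preds = predict_all(model, X, list(range(len(X))))
        assert len(preds) == len(X)
        for p in preds:
            assert sum(p.scores.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in p.scores.values())
            assert p.confidence == p.scores[p.predicted_class]

    def test_dimension_mismatch_rejected(self):
        train = _gaussian_training(n_per_class=20)
        model, _ = train_and_select(train, k=5, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict_all(model, np.zeros((3, 4)), [0, 1, 2])

    def test_exact_tie_broken_by_class_name_and_flagged(self):
        class Coin:
            classes_ = np.array(["alpha", "beta"])
            n_features_in_ = 2

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        preds = predict_all(Coin(), np.zeros((2, 2)), [0, 1])
        for p in preds:
            assert p.predicted_class == "alpha"
            assert p.ambiguous


def _mk_pred(label, cls, conf, slide="s0", excluded=False):
    other = 1.0 - conf
    return PhenotypePrediction(
        slide_id=slide, nucleus_label=label, predicted_class=cls,
        confidence=conf, scores={cls: conf, "other": other},
        excluded=excluded, exclusion_reason="x" if excluded else "",
    )


class TestRankAndPick:
    def test_quota_exact_with_threshold_property(self):
        rng = np.random.default_rng(0)
        confs = rng.uniform(0.5, 1.0, 500)
        preds = [_mk_pred(i, "A", c) for i, c in enumerate(confs)]
        sel = rank_and_pick(preds, per_class_quota=200, target_classes=["A"])
        assert len(sel.cells) == 200
        picked = set(sel.cells["nucleus_label"])
        sel_conf = [p.confidence for p in preds if p.nucleus_label in picked]
        rest = [p.confidence for p in preds if p.nucleus_label not in picked]
        assert min(sel_conf) >= max(rest)
        assert sel.shortfalls == {}

    def test_underquota_returns_all_with_shortfall(self):
        preds = [_mk_pred(i, "A", 0.6 + i * 1e-3) for i in range(50)]
        sel = rank_and_pick(preds, per_class_quota=200, target_classes=["A"])
        assert len(sel.cells) == 50
        assert sel.shortfalls == {"A": 150}

    def test_tie_break_deterministic(self):
        preds = [_mk_pred(i, "A", 0.7, slide=s)
                 for s in ("s1", "s0") for i in (5, 2)]
        sel = rank_and_pick(preds, per_class_quota=3, target_classes=["A"])
        rows = list(map(tuple, sel.cells[["slide_id", "nucleus_label"]].values))
        assert rows == [("s0", 2), ("s0", 5), ("s1", 2)]

    def test_selection_monotone_in_confidence(self):
        rng = np.random.default_rng(3)
        preds = [_mk_pred(i, "A", c)
                 for i, c in enumerate(rng.uniform(0.5, 1.0, 300))]
        sel = rank_and_pick(preds, per_class_quota=100, target_classes=["A"])
        picked = set(sel.cells["nucleus_label"])
        target = sorted(picked)[0]
        boosted = [
            _mk_pred(p.nucleus_label, "A",
                     min(0.999, p.confidence + (0.2 if p.nucleus_label == target
                                                else 0.0)))
            for p in preds
        ]
        sel2 = rank_and_pick(boosted, per_class_quota=100,
                             target_classes=["A"])
        assert target in set(sel2.cells["nucleus_label"])

    def test_excluded_and_discard_never_selected(self):
        preds = [
            _mk_pred(0, "A", 0.99, excluded=True),
            _mk_pred(1, "A", 0.80),
            PhenotypePrediction("s0", 2, DISCARD_CLASS, 0.95,
                                {DISCARD_CLASS: 0.95, "A": 0.05},
                                excluded=True, exclusion_reason=DISCARD_CLASS),
        ]
        sel = rank_and_pick(preds, per_class_quota=10, target_classes=["A"])
        assert list(sel.cells["nucleus_label"]) == [1]
        with pytest.raises(ValueError, match="discard"):
            rank_and_pick(preds, per_class_quota=10,
                          target_classes=[DISCARD_CLASS])

    def test_unknown_class_rejected(self):
        preds = [_mk_pred(0, "A", 0.9)]
        with pytest.raises(ValueError, match="unknown class"):
            rank_and_pick(preds, per_class_quota=5, target_classes=["Z"])


class TestTrainingSetValidation:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            TrainingSet(np.zeros((4, 3)), np.array(["a"] * 4), ("a", "b"))

    def test_label_outside_declared_set(self):
        with pytest.raises(ValueError, match="outside"):
            TrainingSet(np.zeros((2, 3)), np.array(["a", "z"]), ("a", "b"))
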
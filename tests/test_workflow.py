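"""Cross-validation planning, training-loop contracts, grid search, metrics."""

import numpy as np
import pandas as pd
import pytest

from obnet.obn_core import ObnConfig, ObnModel
from obnet.synthetic import SynthSpec, generate_classification_set
from obnet.workflow import (Dataset, EvalReport, TrainRun,
                            dataset_from_samples, evaluate, grid_search,
                            make_cv_plan, predict_proba, train)


def _auc_pair_oracle(y, s):
    """Brute force over all positive-negative pairs, ties count 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCvPlan:
    def test_leave_one_group_out(self):
        plan = make_cv_plan(np.arange(10), np.arange(10), folds=10, seed=0)
        assert sorted(plan.assignments) == list(range(10))

    def test_no_group_straddles_folds(self, rng):
        groups = rng.integers(0, 17, 80)
        plan = make_cv_plan(np.arange(80), groups, folds=4, seed=1)
        for g in np.unique(groups):
            assert len(np.unique(plan.assignments[groups == g])) == 1

    def test_deterministic_and_balanced(self, rng):
        groups = np.repeat(np.arange(20), 3)
        a = make_cv_plan(np.arange(60), groups, folds=5, seed=7)
        b = make_cv_plan(np.arange(60), groups, folds=5, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        sizes = np.bincount(a.assignments)
        assert sizes.max() - sizes.min() <= 3  # within one group of 3

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(np.arange(4), np.arange(4), folds=5)


@pytest.fixture(scope="module")
def small_data():
    return dataset_from_samples(
        generate_classification_set(SynthSpec(n=60, seed=11)))


class TestTrain:
    def test_history_and_early_stopping_contract(self, small_data):
        cfg = ObnConfig(input_size=64, seed=0, lambda_=0.1)
        model = ObnModel(cfg)
        run = train(model, small_data, cfg, lr=1e-3, epochs=4, batch_size=16)
        assert len(run.history) == 4
        assert {"l_att", "l_per", "l_ope", "val_accuracy"} <= set(run.history.columns)
        best = run.history.val_accuracy.max()
        assert run.best_val_accuracy == best
        assert run.history.val_accuracy[run.best_epoch] == best

    def test_zero_weight_maps_zero_operation_loss(self, small_data):
        data = Dataset(images=small_data.images, labels=small_data.labels,
                       weight_maps=np.zeros_like(small_data.weight_maps))
        cfg = ObnConfig(input_size=64, seed=0, lambda_=0.1)
        run = train(ObnModel(cfg), data, cfg, lr=1e-3, epochs=2, batch_size=16)
        assert (run.history.l_ope == 0).all()

    def test_missing_weight_maps_rejected_when_penalized(self, small_data):
        data = Dataset(images=small_data.images, labels=small_data.labels)
        cfg = ObnConfig(input_size=64, seed=0, lambda_=0.1)
        with pytest.raises(ValueError):
            train(ObnModel(cfg), data, cfg, epochs=1)

    def test_training_loss_decreases(self, small_data):
        cfg = ObnConfig(input_size=64, seed=0, lambda_=0.0)
        run = train(ObnModel(cfg), small_data, cfg, lr=1e-3, epochs=6,
                    batch_size=16)
        assert run.history.total.iloc[-1] < run.history.total.iloc[0]


class TestGridSearch:
    @staticmethod
    def _fake_run(acc):
        def make(lam, lr):
            return TrainRun(cfg=ObnConfig(lambda_=lam), lr=lr, epochs=1,
                            batch_size=1, history=pd.DataFrame(),
                            best_epoch=0, best_val_accuracy=acc[(lam, lr)])
        return make

    def test_selects_known_argmax(self):
        acc = {(0.1, 1e-3): 0.7, (0.1, 1e-4): 0.9,
               (0.01, 1e-3): 0.8, (0.01, 1e-4): 0.6}
        best, table = grid_search(None, [0.1, 0.01], [1e-3, 1e-4],
                                  ObnConfig(), train_fn=self._fake_run(acc))
        assert (best.cfg.lambda_, best.lr) == (0.1, 1e-4)
        assert len(table) == 4

    def test_tie_breaks_toward_smaller_lambda_then_lr(self):
        acc = {(0.1, 1e-3): 0.8, (0.1, 1e-4): 0.8,
               (0.01, 1e-3): 0.8, (0.01, 1e-4): 0.8}
        best, _ = grid_search(None, [0.1, 0.01], [1e-3, 1e-4], ObnConfig(),
                              train_fn=self._fake_run(acc))
        assert (best.cfg.lambda_, best.lr) == (0.01, 1e-4)

    def test_single_point_grid(self):
        acc = {(0.5, 1e-2): 0.4}
        best, table = grid_search(None, [0.5], [1e-2], ObnConfig(),
                                  train_fn=self._fake_run(acc))
        assert best.best_val_accuracy == 0.4 and len(table) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(None, [], [1e-3], ObnConfig())


class _ScoreStub:
    """Model stand-in emitting fixed positive-class probabilities."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)
        self.cfg = ObnConfig()


def _report_from_scores(scores, labels, threshold=0.5):
    import obnet.workflow as wf

    stub = _ScoreStub(scores)
    orig = wf.predict_proba
    wf.predict_proba = lambda model, images, batch_size=64: np.c_[
        1 - model.scores, model.scores]
    try:
        return wf.evaluate(stub, Dataset(images=np.zeros((len(labels), 4, 4)),
                                         labels=np.asarray(labels)),
                           threshold=threshold)
    finally:
        wf.predict_proba = orig


class TestEvaluate:
    def test_perfect_scores_give_all_ones(self):
        rep = _report_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.auc) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_perfect_ranking_auc(self):
        rep = _report_from_scores([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert rep.auc == 1.0

    def test_partial_ranking_auc_075(self):
        # one of the four positive-negative pairs is mis-ranked
        rep = _report_from_scores([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0])
        assert rep.auc == pytest.approx(0.75)
        assert rep.auc == pytest.approx(
            _auc_pair_oracle([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1]))

    def test_auc_matches_pair_counting_on_random_sets(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 2)  # coarse scores force ties
            rep = _report_from_scores(s, y)
            assert rep.auc == pytest.approx(_auc_pair_oracle(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            _report_from_scores([0.4, 0.6], [1, 1])

    def test_confusion_consistent_with_rates(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        rep = _report_from_scores(rng.random(30), y)
        c = rep.confusion
        assert rep.sensitivity == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        assert rep.specificity == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))


def test_multilabel_reports_per_label_auc(rng):
    from obnet.nn.functional import softmax  # noqa: F401  (sanity import)

    cfg = ObnConfig(input_size=64, seed=0, multilabel=True, num_classes=3,
                    lambda_=0.0)
    model = ObnModel(cfg)
    data = Dataset(images=rng.random((12, 64, 64)),
                   labels=rng.integers(0, 2, (12, 3)))
    data.labels[0] = [0, 0, 0]
    data.labels[1] = [1, 1, 1]
    rep = evaluate(model, data)
    assert set(rep.per_label_auc) == {0, 1, 2}
    assert rep.auc == pytest.approx(np.mean(list(rep.per_label_auc.values())))
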
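import numpy as np
import pytest

from methylpred.dataset import LabeledDataset, WindowRecord
from methylpred.errors import DataError
from methylpred.evaluation import (
    chromosome_holdout_split,
    confusion_metrics,
    evaluate_predictions,
    roc_auc,
    target_jackknife,
)


def pair_count_auc(labels, scores):
    # oracle: concordant pairs / (n_pos * n_neg), ties count one half
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        y = [1] * 50 + [0] * 50
        rep = confusion_metrics(y, y)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (50, 50, 0, 0)
        assert rep.acc == rep.mcc == rep.sn == rep.sp == 1.0

    def test_all_positive_on_balanced(self):
        y = [1] * 50 + [0] * 50
        rep = confusion_metrics(y, [1] * 100)
        assert (rep.sn, rep.sp, rep.acc, rep.mcc) == (1.0, 0.0, 0.5, 0.0)

    def test_hand_computed_case(self):
        # TP=3, FP=1, TN=4, FN=2
        y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        p = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        rep = confusion_metrics(y, p)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 4, 2)
        assert rep.acc == pytest.approx(0.7)
        assert rep.sn == pytest.approx(3 / 5)
        assert rep.sp == pytest.approx(4 / 5)
        assert rep.mcc == pytest.approx((3 * 4 - 1 * 2) / np.sqrt(4 * 5 * 5 * 6))

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            confusion_metrics([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        pts, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 4000)
        s = rng.uniform(size=4000)
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_matches_pair_counting_oracle(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1  # both classes present
        s = np.round(rng.uniform(size=50), 1)  # coarse grid forces ties
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(pair_count_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1, 1], [0.2, 0.3])


class _MajorityTrainer:
    """Dummy: always predicts the majority training class with score 0/1."""

    def __call__(self, X, y):
        self.majority = int(np.bincount(y.astype(int)).argmax())
        return self

    def predict_proba(self, X):
        return np.full(len(X), float(self.majority))


class TestTargetJackknife:
    def make_data(self, rng, n_real=30, n_synth=10):
        X = rng.normal(size=(n_real + n_synth, 3))
        y = rng.integers(0, 2, n_real + n_synth)
        y[:5], y[5:10] = 1, 0
        origins = np.array(["real"] * n_real + ["synthetic"] * n_synth)
        return X, y, origins

    def test_rounds_equal_real_count_and_synthetics_never_tested(self, rng):
        X, y, origins = self.make_data(rng)
        tested = []

        class Recorder:
            def __call__(self, Xtr, ytr):
                tested.append(len(Xtr))
                return self

            def predict_proba(self, Xq):
                return np.full(len(Xq), 0.5)

        rep = target_jackknife(X, y, origins, Recorder())
        assert rep.n_rounds == 30  # one per real sample
        assert all(n == len(X) - 1 for n in tested)  # synthetic rows always train
        assert rep.tp + rep.tn + rep.fp + rep.fn == 30

    def test_no_synthetic_reduces_to_loo(self, rng):
        X, y, _ = self.make_data(rng, n_real=20, n_synth=0)
        origins = np.array(["real"] * 20)
        rep = target_jackknife(X, y, origins, _MajorityTrainer())
        assert rep.n_rounds == 20

    def test_majority_dummy_confusion(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array([1] * 10 + [0] * 20)
        origins = np.array(["real"] * 30)
        rep = target_jackknife(X, y, origins, _MajorityTrainer())
        # dummy always predicts the (unchanged) majority class 0
        assert rep.sn == 0.0 and rep.sp == 1.0

    def test_no_real_samples_rejected(self, rng):
        X, y, _ = self.make_data(rng)
        with pytest.raises(DataError):
            target_jackknife(X, y, np.array(["synthetic"] * len(X)), _MajorityTrainer())


class TestChromosomeHoldout:
    def make_ds(self):
        recs = [
            WindowRecord("a", "ACGTA", 1, chromosome="chr3", position=10),
            WindowRecord("b", "CCGTA", 0, chromosome="4", position=20),
            WindowRecord("c", "GCGTA", 1, chromosome="chrX", position=30),
            WindowRecord("d", "TCGTA", 0, chromosome="11", position=40),
            WindowRecord("e", "ACGTT", 0, chromosome="chr2", position=50),
        ]
        return LabeledDataset(recs)

    def test_routing(self):
        train, test, excluded = chromosome_holdout_split(self.make_ds())
        assert {r.identifier for r in train} == {"a", "d"}
        assert {r.identifier for r in test} == {"b", "e"}
        assert [r.identifier for r in excluded] == ["c"]

    def test_missing_coordinates_rejected(self):
        ds = LabeledDataset([WindowRecord("a", "ACGTA", 1)])
        with pytest.raises(DataError):
            chromosome_holdout_split(ds)


def test_evaluate_predictions_combines_both_views():
    y = [1, 1, 0, 0]
    s = [0.9, 0.6, 0.4, 0.1]
    rep = evaluate_predictions(y, s)
    assert rep.acc == 1.0 and rep.auc == 1.0
    assert rep.roc_points[0] == (0.0, 0.0)
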
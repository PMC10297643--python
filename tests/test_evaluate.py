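"""Evaluation protocol: folds, confusion metrics, ROC/AUC, localization."""

import numpy as np
import pytest

from cpcnn.evaluate import (
    ConfusionCounts,
    compute_metrics,
    cross_validate,
    localization_score,
    make_folds,
    precision_from_counts,
    roc_auc,
)
from cpcnn.phantoms import PhantomSpec, generate_dataset


def mann_whitney_auc(labels, scores):
    """Brute-force pairwise oracle: wins + half-ties over all pos/neg pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestMakeFolds:
    def test_even_split(self):
        split = make_folds([0, 1] * 5, k=5, seed=0)
        assert sorted(len(f) for f in split.folds) == [2] * 5

    def test_1396_cases_give_paper_fold_sizes(self):
        labels = np.array([1] * 680 + [0] * 716)
        split = make_folds(labels, k=5, seed=3)
        assert sorted(len(f) for f in split.folds) == [279, 279, 279, 279, 280]

    def test_stratification_exact_when_divisible(self):
        labels = np.array([1] * 6 + [0] * 4)
        split = make_folds(labels, k=2, seed=1)
        for fold in split.folds:
            fold_labels = labels[np.asarray(fold)]
            assert (fold_labels == 1).sum() == 3
            assert (fold_labels == 0).sum() == 2

    def test_folds_disjoint_and_cover(self):
        labels = (np.arange(23) % 2).tolist()
        split = make_folds(labels, k=5, seed=7)
        flat = [i for f in split.folds for i in f]
        assert len(flat) == len(set(flat)) == 23

    def test_seed_reproducible(self):
        labels = (np.arange(40) % 2).tolist()
        a = make_folds(labels, k=5, seed=9)
        b = make_folds(labels, k=5, seed=9)
        c = make_folds(labels, k=5, seed=10)
        assert [list(f) for f in a.folds] == [list(f) for f in b.folds]
        assert [list(f) for f in a.folds] != [list(f) for f in c.folds]

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds([0, 1, 0], k=5)

    def test_rotation_never_tests_on_training_fold(self):
        labels = (np.arange(20) % 2).tolist()
        split = make_folds(labels, k=4, seed=2)
        for _, test_ids, train_ids in split.rotation():
            assert not set(test_ids) & set(train_ids)
            assert sorted(set(test_ids) | set(train_ids)) == list(range(20))


class TestComputeMetrics:
    @pytest.mark.parametrize("counts,expected", [
        # published confusion rows that are arithmetically self-consistent
        ((548, 654, 62, 132),
         dict(acc=0.861, pre=0.8984, recall=0.8059, spe=0.9134, f1=0.8496)),
        ((558, 627, 89, 122),
         dict(acc=0.8489, pre=0.8624, recall=0.8206, spe=0.8757, f1=0.841)),
        ((558, 633, 83, 122),
         dict(acc=0.8532, pre=0.8705, recall=0.8206, spe=0.8841, f1=0.8448)),
        ((1, 1, 1, 1), dict(acc=0.5, pre=0.5, recall=0.5, spe=0.5, f1=0.5)),
    ])
    def test_metric_arithmetic(self, counts, expected):
        rep = compute_metrics(ConfusionCounts(*counts)).rounded(4)
        for name, value in expected.items():
            assert rep[name] == pytest.approx(value, abs=5e-5), name

    def test_zero_denominator_reported_as_undefined(self):
        rep = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
        assert rep.pre is None
        assert any("precision undefined" in f for f in rep.flags)
        assert rep.acc == pytest.approx(5 / 8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=1, fp=1, fn=1)

    def test_counts_from_predictions(self):
        c = ConfusionCounts.from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]).auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4).auc == pytest.approx(0.5)

    def test_worked_example(self):
        # 3 of 4 positive/negative pairs won
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]).auc == pytest.approx(0.75)

    def test_single_class_rejected_naming_class(self):
        with pytest.raises(ValueError, match="class 0"):
            roc_auc([1, 1, 1], [0.2, 0.5, 0.9])

    def test_curve_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        curve = roc_auc(labels, scores)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_sweep_equals_mann_whitney(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            assert roc_auc(labels, scores).auc == pytest.approx(
                mann_whitney_auc(labels, scores), abs=1e-9)


class TestReaderPrecision:
    @pytest.mark.parametrize("correct,total,expected", [
        (181, 200, 90.50),
        (195, 200, 97.50),
        (191, 200, 95.50),
        (0, 200, 0.0),
    ])
    def test_percentages(self, correct, total, expected):
        assert precision_from_counts(correct, total) == pytest.approx(expected)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            precision_from_counts(201, 200)
        with pytest.raises(ValueError):
            precision_from_counts(-1, 200)
        with pytest.raises(ValueError):
            precision_from_counts(1, 0)


class TestLocalizationScore:
    def test_peak_inside_mask_hits(self):
        mask = np.zeros((32, 64), bool)
        mask[10:12, 20:24] = True
        heat = np.zeros((32, 64))
        heat[11, 22] = 1.0
        assert localization_score(heat, mask)

    def test_peak_far_from_mask_misses(self):
        mask = np.zeros((64, 64), bool)
        mask[5:7, 5:7] = True
        heat = np.zeros((64, 64))
        heat[60, 60] = 1.0
        assert not localization_score(heat, mask, dilation_radius=9)

    def test_uniform_map_ties_break_to_first_raster_index(self):
        near = np.zeros((32, 32), bool)
        near[2:4, 2:4] = True  # dilated region covers (0, 0)
        far = np.zeros((32, 32), bool)
        far[25:27, 25:27] = True
        uniform = np.ones((32, 32))
        assert localization_score(uniform, near, dilation_radius=9)
        assert not localization_score(uniform, far, dilation_radius=9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            localization_score(np.ones((8, 8)), np.zeros((8, 8), bool))

    def test_random_hit_rate_matches_dilated_area_fraction(self, rng):
        from scipy import ndimage

        mask = np.zeros((40, 20), bool)
        mask[18:22, 8:12] = True
        disk = (lambda r: (np.add.outer(np.arange(-r, r + 1) ** 2,
                                        np.arange(-r, r + 1) ** 2) <= r * r))(9)
        frac = ndimage.binary_dilation(mask, structure=disk).mean()
        trials = 1000
        hits = sum(
            localization_score(rng.random((40, 20)), mask, dilation_radius=9)
            for _ in range(trials)
        )
        se = np.sqrt(frac * (1 - frac) / trials)
        assert abs(hits / trials - frac) <= 3 * se


class TestCrossValidate:
    class _ConstantModel:
        pass

    @staticmethod
    def _constant_train(cases, config):
        return TestCrossValidate._ConstantModel()

    @staticmethod
    def _constant_predict(model, cases):
        from cpcnn.cascade import Prediction
        from cpcnn.weakloc import LocalizationMap

        loc = LocalizationMap(values=np.zeros((4, 8)), native=np.zeros((2, 4)))
        return [Prediction(label=1, probability=1.0, localization=loc,
                           primary_scores=np.array([0.0, 1.0]),
                           final_scores=np.array([0.0, 1.0])) for _ in cases]

    @pytest.fixture(scope="class")
    def toy_cases(self):
        class Case:
            def __init__(self, label):
                self.label = label
                self.pyramid = None

        return [Case(i % 2) for i in range(20)]

    def test_constant_classifier_recall_one_spe_zero(self, toy_cases):
        result = cross_validate(toy_cases, config=None, k=4, seed=0,
                                train_fn=self._constant_train,
                                predict_fn=self._constant_predict)
        for rep in result.per_fold:
            assert rep.recall == 1.0
            assert rep.spe == 0.0
        # constant scores make AUC the all-ties value
        assert result.mean.auc == pytest.approx(0.5)

    def test_mean_equals_arithmetic_mean_of_folds(self, toy_cases):
        result = cross_validate(toy_cases, config=None, k=4, seed=0,
                                train_fn=self._constant_train,
                                predict_fn=self._constant_predict)
        accs = [rep.acc for rep in result.per_fold]
        assert result.mean.acc == pytest.approx(np.mean(accs))

    def test_every_case_tested_exactly_once(self, toy_cases):
        seen = []
        recorded_train = []

        def record_train(cases, config):
            recorded_train.append({id(c) for c in cases})
            return self._ConstantModel()

        def record_predict(model, cases):
            seen.extend(id(c) for c in cases)
            return self._constant_predict(model, cases)

        cross_validate(toy_cases, config=None, k=5, seed=1,
                       train_fn=record_train, predict_fn=record_predict)
        assert sorted(seen) == sorted(id(c) for c in toy_cases)
        for fold_train, fold_test in zip(recorded_train,
                                         np.array_split(seen, 5)):
            assert not fold_train & set(fold_test)

    def test_scaled_down_phantom_cross_validation_recovers(self):
        """5-fold rotation on reduced-resolution phantoms reaches a mean
        held-out AUC of at least 0.85."""
        from cpcnn.cascade import CascadeConfig

        cases = generate_dataset(PhantomSpec(base_resolution=(96, 48), seed=61), 100)
        config = CascadeConfig.tiny(base_size=(96, 48), epochs_primary=3,
                                    epochs_cascade=4, seed=6)
        result = cross_validate(cases, config, k=5, seed=6)
        assert result.mean.auc is not None
        assert result.mean.auc >= 0.85
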
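"""Metrics, ROC/PR, repeated cross-validation, resolution analysis."""

import math

import numpy as np
import pytest

from i5hmcvec import (
    ConfusionCounts,
    GenomicInterval,
    confusion,
    metrics,
    repeated_cv,
    resolution_analysis,
    roc_pr,
)
from i5hmcvec.errors import InvalidInputError


def brute_force_metrics(tp, tn, fp, fn):
    """Independent oracle: direct transcription of the four formulas."""
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(
        (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    )
    return sen, spe, acc, mcc


def pair_counting_auroc(y, s):
    """Mann-Whitney statistic: fraction of correctly ordered (+,-) pairs."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct(self):
        y = np.array([1] * 5 + [0] * 5)
        cc = confusion(y, y)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (5, 5, 0, 0)

    def test_label_swap_symmetry(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        cc = confusion(y, p)
        swapped = confusion(y, 1 - p)
        assert (swapped.tp, swapped.fn) == (cc.fn, cc.tp)
        assert (swapped.tn, swapped.fp) == (cc.fp, cc.tn)

    def test_total_preserved(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        assert confusion(y, p).total == 50

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.sen, m.spe, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_evaluated_case(self):
        m = metrics(ConfusionCounts(tp=40, tn=35, fp=15, fn=10))
        assert m.sen == pytest.approx(0.8)
        assert m.spe == pytest.approx(0.7)
        assert m.acc == pytest.approx(0.75)
        assert m.mcc == pytest.approx(1250 / math.sqrt(6187500), abs=1e-9)

    def test_no_association_gives_zero_mcc(self):
        m = metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert m.mcc == 0.0 and m.mcc_defined

    def test_zero_denominator_flagged(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m.mcc == 0.0 and not m.mcc_defined

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(1, 200, 4)
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            ref = brute_force_metrics(tp, tn, fp, fn)
            assert np.allclose((m.sen, m.spe, m.acc, m.mcc), ref, atol=1e-12)

    def test_accuracy_is_prevalence_weighted_sen_spe(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 100, 4))
            m = metrics(ConfusionCounts(tp, tn, fp, fn))
            n_pos, n_neg = tp + fn, tn + fp
            expected = (n_pos * m.sen + n_neg * m.spe) / (n_pos + n_neg)
            assert m.acc == pytest.approx(expected, abs=1e-12)


class TestRocPr:
    def test_perfect_ranking(self):
        res = roc_pr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert res.auroc == 1.0 and res.aupr == 1.0

    def test_anti_ranking(self):
        res = roc_pr([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert res.auroc == 0.0

    def test_four_sample_hand_case(self):
        res = roc_pr([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1])
        assert res.auroc == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_pr([1, 1, 1], [0.1, 0.2, 0.3])

    def test_auroc_equals_pair_counting_statistic(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.permutation(n).astype(float)  # tie-free scores
            assert roc_pr(y, s).auroc == pytest.approx(
                pair_counting_auroc(y, s), abs=1e-12
            )


class _StubModel:
    """Records the rows it is asked to score; predicts the row sum sign."""

    def __init__(self, log):
        self.log = log

    def fit(self, X, y):
        return self

    def predict(self, X):
        self.log.append(np.sort(X[:, 0]).tolist())
        return (X.sum(axis=1) > 0).astype(int)

    def decision_scores(self, X):
        return X.sum(axis=1)


class TestRepeatedCV:
    @staticmethod
    def _toy(n=30, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(-1, 1, (n // 2, 3)), rng.normal(1, 1, (n // 2, 3))]
        )
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_repeats_times_folds_models_fitted(self):
        X, y = self._toy()
        fits = []

        def factory(seed):
            fits.append(seed)
            return _StubModel([])

        repeated_cv(X, y, factory, repeats=3, folds=5, seed=0)
        assert len(fits) == 15

    def test_each_sample_tested_once_per_repeat(self):
        X, y = self._toy(n=20, seed=1)
        X[:, 0] = np.arange(20)  # unique row identifiers
        log = []
        repeated_cv(X, y, lambda s: _StubModel(log), repeats=2, folds=4, seed=0)
        per_repeat = [log[:4], log[4:]]
        for chunks in per_repeat:
            seen = sorted(x for chunk in chunks for x in chunk)
            assert seen == list(range(20))

    def test_fixed_seed_reproduces_report(self):
        from i5hmcvec import SVMClassifier

        X, y = self._toy()
        factory = lambda s: SVMClassifier(c=1.0, gamma=0.5, seed=s)
        r1 = repeated_cv(X, y, factory, repeats=2, folds=5, seed=9)
        r2 = repeated_cv(X, y, factory, repeats=2, folds=5, seed=9)
        assert r1.per_repeat.equals(r2.per_repeat)

    def test_reported_mean_matches_per_repeat_table(self):
        X, y = self._toy()
        report = repeated_cv(
            X, y, lambda s: _StubModel([]), repeats=4, folds=5, seed=2
        )
        assert report.mean["acc"] == pytest.approx(
            report.per_repeat["acc"].mean()
        )

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(InvalidInputError):
            repeated_cv(X, np.ones(10, int), lambda s: _StubModel([]))


class _ConstantModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(X.shape[0], self.label, dtype=int)

    def decision_scores(self, X):
        return np.full(X.shape[0], float(self.label))


class TestResolutionAnalysis:
    @pytest.fixture(scope="class")
    def pool(self):
        rng = np.random.default_rng(4)
        genome = {"c": "".join(rng.choice(list("ACGT"), 20_000))}
        pool = [GenomicInterval("c", 0, 20_000, "+", id="pool")]
        return genome, pool

    def test_always_negative_model_has_unit_spe(self, pool, multik_small):
        genome, intervals = pool
        table = resolution_analysis(
            _ConstantModel(0), genome, intervals, multik_small,
            length_grid=[50, 200], n_per_length=10, seed=0,
        )
        assert (table["spe"] == 1.0).all()

    def test_always_positive_model_has_zero_spe(self, pool, multik_small):
        genome, intervals = pool
        table = resolution_analysis(
            _ConstantModel(1), genome, intervals, multik_small,
            length_grid=[50, 200], n_per_length=10, seed=0,
        )
        assert (table["spe"] == 0.0).all()

    def test_infeasible_length_skipped_with_warning(self, pool, multik_small, caplog):
        genome, intervals = pool
        with caplog.at_level("WARNING"):
            table = resolution_analysis(
                _ConstantModel(0), genome, intervals, multik_small,
                length_grid=[100, 50_000], n_per_length=5, seed=0,
            )
        assert table["length"].tolist() == [100]
        assert "skipped" in caplog.text

    def test_excluded_regions_never_sampled(self, multik_small):
        rng = np.random.default_rng(5)
        genome = {"c": "".join(rng.choice(list("ACGT"), 5_000))}
        pool = [GenomicInterval("c", 0, 5_000, "+")]
        exclude = [GenomicInterval("c", 0, 2_500, "+")]

        class Recorder(_ConstantModel):
            pass

        # windows of 2600 cannot fit outside the excluded half
        table = resolution_analysis(
            Recorder(0), genome, pool, multik_small,
            length_grid=[2600], n_per_length=3, exclude=exclude, seed=0,
        )
        assert table.empty or (table["n"] == 0).all()
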
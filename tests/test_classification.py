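"""Cross-validated SVM evaluation, subset enumeration and search, metrics."""

import numpy as np
import pandas as pd
import pytest

import dtcwt_radiomics as dr
from dtcwt_radiomics.classification import ExhaustiveSubsetSVC
from dtcwt_radiomics.errors import ConfigurationError, InputError


def make_table(X, y, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    table = pd.DataFrame(X, columns=names)
    table.insert(0, "label", y)
    return table


@pytest.fixture()
def study_labels():
    return np.array([1] * 27 + [0] * 24)


class TestStratifiedFolds:
    def test_study_layout_fold_sizes(self, study_labels):
        folds = dr.stratified_folds(study_labels, 5, seed=0)
        sizes = sorted(np.bincount(folds), reverse=True)
        assert sizes == [11, 10, 10, 10, 10]
        pos_per_fold = np.bincount(folds[study_labels == 1])
        assert set(pos_per_fold) <= {5, 6}

    def test_leave_one_out_degenerate(self):
        y = np.array([1, 0, 1, 0])
        folds = dr.stratified_folds(y, 4, seed=1)
        assert sorted(np.bincount(folds)) == [1, 1, 1, 1]

    def test_deterministic_given_seed(self, study_labels):
        a = dr.stratified_folds(study_labels, 5, seed=3)
        b = dr.stratified_folds(study_labels, 5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(InputError):
            dr.stratified_folds(np.array([1, 1, 0, 0, 0]), 3, seed=0)


class TestMetrics:
    def test_all_correct(self):
        m = dr.classification_metrics(tp=10, fp=0, tn=10, fn=0)
        assert m["acc"] == m["sen"] == m["spc"] == m["f1"] == 1.0

    @pytest.mark.parametrize(
        "confusion,acc,sen,spc",
        [
            ((21, 3, 21, 6), 82.35, 77.78, 87.50),
            ((22, 2, 22, 5), 86.27, 81.48, 91.67),
        ],
    )
    def test_percent_values(self, confusion, acc, sen, spc):
        tp, fp, tn, fn = confusion
        m = dr.classification_metrics(tp, fp, tn, fn)
        assert round(100 * m["acc"], 2) == acc
        assert round(100 * m["sen"], 2) == sen
        assert round(100 * m["spc"], 2) == spc

    def test_trivial_rejector(self):
        m = dr.classification_metrics(tp=0, fp=0, tn=24, fn=27)
        assert m["acc"] == 24 / 51 and m["sen"] == 0.0 and m["spc"] == 1.0
        assert "f1" in m["undefined"] or m["f1"] == 0.0


class TestAuc:
    def test_perfect_ranking(self):
        assert dr.auc_mann_whitney([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert dr.auc_mann_whitney([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_four_pair_example(self):
        auc = dr.auc_mann_whitney([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == 0.75

    def test_agrees_with_brute_force_pairs(self, rng):
        for _ in range(30):
            y = rng.integers(0, 2, 20)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=20), 1)  # rounded -> ties happen
            pos, neg = s[y == 1], s[y == 0]
            pairs = sum(
                1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
            )
            np.testing.assert_allclose(
                dr.auc_mann_whitney(s, y), pairs / (pos.size * neg.size), atol=1e-12
            )

    def test_agrees_with_sklearn_roc_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        y = np.array([1] * 12 + [0] * 15)
        s = rng.normal(size=27)
        np.testing.assert_allclose(dr.auc_mann_whitney(s, y), roc_auc_score(y, s),
                                   atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            dr.auc_mann_whitney([1, 2], [1, 1])


class TestConfidenceIntervals:
    def test_wilson_boundaries(self):
        assert dr.wilson_ci(0, 10)[0] == 0.0
        assert dr.wilson_ci(10, 10)[1] == 1.0

    def test_wilson_42_of_51(self):
        # closed form with z = 1.95996: center (p + z^2/2n)/(1 + z^2/n),
        # half-width z/(1 + z^2/n) * sqrt(pq/n + z^2/4n^2)
        lo, hi = dr.wilson_ci(42, 51, 0.95)
        np.testing.assert_allclose([lo, hi], [0.697455, 0.904283], atol=1e-5)

    def test_bootstrap_perfect_separation_degenerate_interval(self):
        scores = np.array([2.0, 3.0, 4.0, -2.0, -3.0, -4.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        lo, hi = dr.bootstrap_auc_ci(scores, labels, bootstrap_reps=200, seed=0)
        assert lo == hi == 1.0

    def test_bootstrap_deterministic_and_nested(self, rng):
        y = np.array([1] * 15 + [0] * 15)
        s = rng.normal(size=30) + y
        a = dr.bootstrap_auc_ci(s, y, 500, seed=4, ci_level=0.95)
        b = dr.bootstrap_auc_ci(s, y, 500, seed=4, ci_level=0.95)
        assert a == b
        point = dr.auc_mann_whitney(s, y)
        widths = []
        for level in (0.80, 0.90, 0.95):
            lo, hi = dr.bootstrap_auc_ci(s, y, 500, seed=4, ci_level=level)
            assert lo <= point <= hi
            widths.append(hi - lo)
        assert widths[0] <= widths[1] <= widths[2]


class TestEnumerateSubsets:
    @pytest.mark.parametrize("n,count", [(6, 63), (9, 511)])
    def test_full_enumeration_count(self, n, count):
        assert sum(1 for _ in dr.enumerate_subsets([f"f{i}" for i in range(n)])) == count

    def test_size_capped_enumeration(self):
        subs = list(dr.enumerate_subsets(["a", "b", "c"], max_subset_size=2))
        assert len(subs) == 6
        assert subs[0] == ("a",) and subs[-1] == ("b", "c")

    def test_size_then_lexicographic_order(self):
        subs = list(dr.enumerate_subsets(["a", "b", "c"]))
        assert subs == [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"),
                        ("b", "c"), ("a", "b", "c")]

    def test_cap_requires_max_subset_size(self):
        with pytest.raises(ConfigurationError):
            next(dr.enumerate_subsets([str(i) for i in range(26)]))


class TestEvaluateSubset:
    def test_perfectly_separated_feature(self, rng, study_labels):
        X = rng.normal(scale=0.1, size=(51, 1)) + 10.0 * (2 * study_labels[:, None] - 1)
        res = dr.evaluate_subset(make_table(X, study_labels), ["f0"])
        assert res.acc == res.sen == res.spc == res.auc == 1.0
        assert res.ci["auc"] == (1.0, 1.0)

    def test_confusion_counts_partition_classes(self, rng, study_labels):
        X = rng.normal(size=(51, 2))
        res = dr.evaluate_subset(make_table(X, study_labels), ["f0", "f1"],
                                 compute_ci=False)
        assert res.tp + res.fn == 27 and res.tn + res.fp == 24
        assert res.acc == (res.tp + res.tn) / 51

    def test_patient_order_invariance_given_fixed_folds(self, rng, study_labels):
        X = rng.normal(size=(51, 3))
        X[study_labels == 1] += 0.8
        table = make_table(X, study_labels)
        folds = dr.stratified_folds(study_labels, 5, seed=9)
        res = dr.evaluate_subset(table, ["f0", "f1"], folds=folds, compute_ci=False)
        perm = rng.permutation(51)
        res_p = dr.evaluate_subset(table.iloc[perm], ["f0", "f1"],
                                   folds=folds[perm], compute_ci=False)
        assert (res.tp, res.fp, res.tn, res.fn) == (res_p.tp, res_p.fp, res_p.tn, res_p.fn)
        np.testing.assert_allclose(res.auc, res_p.auc)

    def test_permutation_null_accuracy_near_prevalence(self, study_labels):
        """Accuracy on permuted labels concentrates near the majority-class
        prevalence (27/51)."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(51, 2))
        accs = []
        for _ in range(30):
            y = rng.permutation(study_labels)
            res = dr.evaluate_subset(make_table(X, y), ["f0", "f1"],
                                     compute_ci=False)
            accs.append(res.acc)
        assert abs(np.mean(accs) - 27 / 51) < 0.1

    def test_constant_feature_warns_not_errors(self, study_labels, rng):
        X = np.concatenate([np.ones((51, 1)), rng.normal(size=(51, 1))], axis=1)
        with pytest.warns(UserWarning):
            res = dr.evaluate_subset(make_table(X, study_labels), ["f0", "f1"],
                                     compute_ci=False)
        assert 0.0 <= res.acc <= 1.0


class TestExhaustiveSearch:
    def test_dominant_singleton_wins_over_noise(self, rng, study_labels):
        X = rng.normal(size=(51, 5))
        X[:, 3] = 10.0 * study_labels + rng.normal(scale=0.1, size=51)
        res = dr.exhaustive_search(make_table(X, study_labels),
                                   [f"f{i}" for i in range(5)])
        assert res.subset == ("f3",)
        assert res.acc == 1.0

    def test_duplicate_feature_tie_broken_by_size(self, rng, study_labels):
        x = 10.0 * study_labels + rng.normal(scale=0.1, size=51)
        X = np.stack([x, x], axis=1)
        res = dr.exhaustive_search(make_table(X, study_labels), ["f0", "f1"])
        assert res.subset == ("f0",)  # singleton beats the identical pair

    def test_nine_feature_group_visits_511_subsets(self, rng, study_labels):
        X = rng.normal(size=(51, 9))
        res = dr.exhaustive_search(make_table(X, study_labels),
                                   [f"f{i}" for i in range(9)])
        assert res.evaluation_count == 511

    def test_search_optimism_on_pure_noise(self):
        """Search-selected best accuracy on label-free noise exceeds the
        majority-class rate: the selection optimism the protocol inherits
        from choosing the winner on its own out-of-fold predictions."""
        accs = []
        y = np.array([1] * 27 + [0] * 24)
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(51, 9))
            res = dr.exhaustive_search(
                make_table(X, y), [f"f{i}" for i in range(9)],
                dr.ModelConfig(seed=seed),
            )
            accs.append(res.acc)
        assert np.mean(accs) > 27 / 51

    def test_estimator_sklearn_api(self, rng, study_labels):
        from sklearn.base import clone

        X = rng.normal(size=(51, 4))
        X[:, 1] += 3.0 * study_labels
        est = ExhaustiveSubsetSVC(seed=0)
        assert clone(est).get_params() == est.get_params()
        est.fit(X, study_labels)
        assert est.best_subset_ == (1,)
        pred = est.predict(X)
        assert pred.shape == (51,) and set(pred) <= {0, 1}
        assert est.decision_function(X).shape == (51,)
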
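"""QSAR grid: splits, feature selection oracles, rebalancing, metrics."""

import math

import numpy as np
import pytest

from skinsens import qsar, synthetic
from skinsens.exceptions import InvalidArgumentError
from skinsens.synthetic import FingerprintDataset


def exact_fisher_two_sided(a, b, c, d):
    """Independent oracle: enumerate hypergeometric tables with fixed margins."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(k):
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    k_min = max(0, col1 - row2)
    k_max = min(col1, row1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(k_min, k_max + 1) if pmf(k) <= p_obs * (1 + 1e-7))


def _dataset(X, y):
    return FingerprintDataset(
        matrix=np.asarray(X, dtype=np.int8),
        labels=np.asarray(y, dtype=int),
        compound_ids=[f"c{i}" for i in range(len(y))],
        feature_ids=[f"f{j}" for j in range(np.asarray(X).shape[1])],
    )


class TestSplit:
    def test_published_partition_sizes(self):
        ds = synthetic.gen_fingerprint_dataset(6520, n_features=10, n_enriched=0, seed=50)
        train, test = qsar.split_dataset(ds, train_fraction=0.7, seed=1)
        assert len(train.labels) == 4564
        assert len(test.labels) == 1956

    def test_small_split(self):
        ds = synthetic.gen_fingerprint_dataset(10, n_features=4, n_enriched=0, active_fraction=0.3, seed=51)
        train, test = qsar.split_dataset(ds, train_fraction=0.7, seed=2)
        assert (len(train.labels), len(test.labels)) == (7, 3)

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = synthetic.gen_fingerprint_dataset(200, n_features=5, n_enriched=0, seed=52)
        train, test = qsar.split_dataset(ds, seed=3)
        assert set(train.compound_ids) | set(test.compound_ids) == set(ds.compound_ids)
        assert not set(train.compound_ids) & set(test.compound_ids)

    def test_stratification_preserves_imbalance(self):
        ds = synthetic.gen_fingerprint_dataset(1000, n_features=5, n_enriched=0, active_fraction=0.1, seed=53)
        train, test = qsar.split_dataset(ds, seed=4)
        assert abs(train.labels.mean() - 0.1) < 0.01
        assert abs(test.labels.mean() - 0.1) < 0.01


class TestFisherSelection:
    def test_pvalues_match_enumeration_oracle(self):
        rng = np.random.default_rng(54)
        for _ in range(200):
            n_act = int(rng.integers(2, 16))
            n_inact = int(rng.integers(2, 16))
            a = int(rng.integers(0, n_act + 1))
            c = int(rng.integers(0, n_inact + 1))
            y = np.array([1] * n_act + [0] * n_inact)
            x = np.zeros(n_act + n_inact, dtype=np.int8)
            x[:a] = 1
            x[n_act : n_act + c] = 1
            p_impl = qsar.fisher_pvalues(x[:, None], y)[0]
            p_oracle = exact_fisher_two_sided(a, n_act - a, c, n_inact - c)
            assert p_impl == pytest.approx(p_oracle, abs=1e-10)

    def test_uninformative_feature_never_selected(self):
        y = np.array([1] * 10 + [0] * 10)
        x = np.tile([1, 0], 10)[:, None]  # same prevalence in both classes
        assert qsar.fisher_pvalues(x, y)[0] == pytest.approx(1.0)
        assert len(qsar.fisher_feature_select(x, y, 0.05)) == 0

    def test_textbook_enrichment_example(self):
        # feature present in 8/10 actives and 2/10 inactives
        y = np.array([1] * 10 + [0] * 10)
        x = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)[:, None]
        p = qsar.fisher_pvalues(x, y)[0]
        assert p == pytest.approx(exact_fisher_two_sided(8, 2, 2, 8), abs=1e-12)


class TestAUCSelection:
    def test_binary_feature_closed_form(self):
        # TPR 0.8, FPR 0.2 -> AUC (0.8 + 0.8)/2 = 0.8
        y = np.array([1] * 10 + [0] * 10)
        x = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)[:, None]
        assert qsar.feature_aucs(x, y)[0] == pytest.approx(0.8)

    def test_independent_feature_excluded_at_052(self):
        y = np.array([1] * 10 + [0] * 10)
        x = np.tile([1, 0], 10)[:, None]
        assert qsar.feature_aucs(x, y)[0] == pytest.approx(0.5)
        assert len(qsar.auc_feature_select(x, y, 0.52)) == 0

    def test_label_identical_feature_is_perfect(self):
        y = np.array([1] * 5 + [0] * 5)
        assert qsar.feature_aucs(y[:, None], y)[0] == pytest.approx(1.0)

    def test_direction_folding_keeps_depletion_features(self):
        y = np.array([1] * 10 + [0] * 10)
        x = (1 - y)[:, None]  # anti-correlated feature
        assert qsar.feature_aucs(x, y)[0] == pytest.approx(1.0)


class TestImportanceSelection:
    def test_planted_perfect_feature_ranks_first(self):
        rng = np.random.default_rng(55)
        y = np.array([1] * 30 + [0] * 30)
        X = rng.integers(0, 2, size=(60, 10)).astype(np.int8)
        X[:, 3] = y  # deterministic feature
        for family in ("random_forest", "gradient_boosted_trees"):
            sel = qsar.importance_feature_select(X, y, family, top_k=1, seed=5)
            assert sel.tolist() == [3]

    def test_topk_cardinality_and_full_selection(self):
        rng = np.random.default_rng(56)
        y = rng.integers(0, 2, size=40)
        X = rng.integers(0, 2, size=(40, 8)).astype(np.int8)
        assert len(qsar.importance_feature_select(X, y, "random_forest", 5, seed=6)) == 5
        assert len(qsar.importance_feature_select(X, y, "random_forest", 8, seed=6)) == 8


class TestRebalance:
    def _imbalanced(self, seed=57):
        rng = np.random.default_rng(seed)
        X = rng.random((100, 6))
        y = np.array([1] * 30 + [0] * 70)
        return X, y

    def test_down_and_up_counts(self):
        X, y = self._imbalanced()
        _, y_down = qsar.rebalance(X, y, "down", seed=1)
        _, y_up = qsar.rebalance(X, y, "up", seed=1)
        assert sorted(np.bincount(y_down)) == [30, 30]
        assert sorted(np.bincount(y_up)) == [70, 70]

    def test_smote_interpolation_property(self):
        X, y = self._imbalanced()
        Xb, yb = qsar.rebalance(X, y, "smote", seed=2)
        assert np.bincount(yb)[0] == np.bincount(yb)[1]
        # every minority point (original or interpolated) lies coordinate-wise
        # inside the minority bounding box: interpolation cannot extrapolate
        X_min = X[y == 1]
        lo, hi = X_min.min(axis=0), X_min.max(axis=0)
        X_min_b = Xb[yb == 1]
        assert (X_min_b >= lo - 1e-12).all() and (X_min_b <= hi + 1e-12).all()

    def test_rose_is_balanced_and_preserves_total(self):
        X, y = self._imbalanced()
        Xb, yb = qsar.rebalance(X, y, "rose", seed=3)
        assert len(yb) == len(y)
        assert abs(int(np.bincount(yb)[0]) - int(np.bincount(yb)[1])) <= 1

    def test_seeded_determinism(self):
        X, y = self._imbalanced()
        a = qsar.rebalance(X, y, "smote", seed=9)
        b = qsar.rebalance(X, y, "smote", seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestClassifiersAndMetrics:
    def test_separable_data_perfect_training_fit_for_trees(self):
        y = np.array([1] * 25 + [0] * 25)
        rng = np.random.default_rng(58)
        X = rng.integers(0, 2, size=(50, 5)).astype(float)
        X[:, 0] = y
        for family in ("random_forest", "gradient_boosted_trees"):
            model = qsar.train_classifier(X, y, family, seed=7)
            ds = _dataset(X, y)
            metrics = qsar.evaluate_external(model, ds)
            assert metrics.auc_roc == pytest.approx(1.0)
            assert metrics.balanced_accuracy == pytest.approx(1.0)

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(59)
        X = rng.integers(0, 2, size=(60, 8)).astype(float)
        y = rng.integers(0, 2, size=60)
        a = qsar.train_classifier(X, y, "random_forest", seed=11)
        b = qsar.train_classifier(X, y, "random_forest", seed=11)
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_external_metrics_formulas(self):
        # confusion TP=40, FP=10, FN=20, TN=30 via a degenerate "model"
        y_true = np.array([1] * 60 + [0] * 40)
        score = np.array([0.9] * 40 + [0.1] * 20 + [0.9] * 10 + [0.1] * 30)

        class Stub:
            def predict_proba(self, X):
                return np.column_stack([1 - score, score])

        ds = _dataset(np.zeros((100, 1)), y_true)
        m = qsar.evaluate_external(Stub(), ds)
        ba = (40 / 60 + 30 / 40) / 2
        mcc = (40 * 30 - 10 * 20) / math.sqrt((40 + 10) * (40 + 20) * (30 + 10) * (30 + 20))
        assert m.balanced_accuracy == pytest.approx(ba)
        assert m.mcc == pytest.approx(mcc)

    def test_constant_predictor_has_zero_mcc(self):
        y_true = np.array([1] * 10 + [0] * 10)

        class Stub:
            def predict_proba(self, X):
                return np.column_stack([np.zeros(len(X)), np.ones(len(X))])

        ds = _dataset(np.zeros((20, 1)), y_true)
        assert qsar.evaluate_external(Stub(), ds).mcc == 0.0


class TestCrossValidation:
    def test_grid_cardinality_and_zero_sd_single_repeat(self):
        ds = synthetic.gen_fingerprint_dataset(
            300, n_features=30, n_enriched=5, odds_ratio=6.0, active_fraction=0.3, seed=60
        )
        specs = [qsar.FeatureSelectionSpec("fisher", 0.05), qsar.FeatureSelectionSpec("auc", 0.56)]
        res = qsar.cross_validate_grid(
            ds, specs, ["none", "up"], ["naive_bayes"], n_repeats=1, seed=8
        )
        assert len(res) == 2 * 2 * 1
        assert (res["auc_sd"] == 0.0).all()

    def test_planted_signal_beats_shuffled_labels(self):
        ds = synthetic.gen_fingerprint_dataset(
            600, n_features=60, n_enriched=10, odds_ratio=8.0,
            base_prevalence=0.1, active_fraction=0.3, seed=61,
        )
        spec = [qsar.FeatureSelectionSpec("fisher", 0.05)]
        signal = qsar.cross_validate_grid(
            ds, spec, ["none"], ["naive_bayes"], n_repeats=3, seed=9
        )["auc_mean"][0]
        rng = np.random.default_rng(62)
        null_ds = FingerprintDataset(
            ds.matrix, rng.permutation(ds.labels), ds.compound_ids, ds.feature_ids
        )
        null = qsar.cross_validate_grid(
            null_ds, spec, ["none"], ["naive_bayes"], n_repeats=3, seed=9
        )["auc_mean"][0]
        assert signal - null >= 0.2

    def test_planted_features_recovered(self):
        ds = synthetic.gen_fingerprint_dataset(
            2000, n_features=100, n_enriched=10, odds_ratio=8.0,
            base_prevalence=0.1, active_fraction=0.3, seed=63,
        )
        sel = qsar.fisher_feature_select(ds.matrix, ds.labels, 0.05)
        recall = len(set(sel) & ds.true_enriched) / len(ds.true_enriched)
        assert recall >= 0.8

    def test_empty_grid_rejected(self):
        ds = synthetic.gen_fingerprint_dataset(50, n_features=5, n_enriched=0, active_fraction=0.4, seed=64)
        with pytest.raises(InvalidArgumentError):
            qsar.cross_validate_grid(ds, [], ["none"], ["naive_bayes"])
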
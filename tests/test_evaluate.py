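import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from radadapt import (FeatureTable, InputError, RFParams, bootstrap_632plus,
                      compute_metrics, loo_predict)
from radadapt.evaluate import auc_trapezoidal, b632plus_from_components

from .oracles import b632plus_brute


def two_cluster_table(n=16, sep=6.0, seed=0, p=3):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[y == 1, 0] += sep
    labels = np.where(y == 1, "adaptive", "non-adaptive").astype(object)
    return FeatureTable(
        feature_names=[f"f{j}" for j in range(p)],
        X=X, labels=labels,
        patient_ids=[f"P{i}" for i in range(n)],
        class_values=("adaptive", "non-adaptive"),
    ), y


def confusion_probs(tp, fn, tn, fp):
    """Pooled probabilities realizing a given confusion matrix at threshold 0.5."""
    probs = np.array([0.9] * tp + [0.1] * fn + [0.1] * tn + [0.9] * fp)
    labels = np.array(["adaptive"] * (tp + fn) + ["non-adaptive"] * (tn + fp),
                      dtype=object)
    return probs, labels


class TestMetrics:
    def test_cohort_worked_example_prevalence_adjusted_ppv_npv(self):
        """accuracy .780 and sensitivity .840 on a 50/41 cohort imply
        TP=42, FN=8, TN=29, FP=12; at pi=0.40 the adjusted predictive values
        are .657/.869 and the raw precision .778."""
        probs, labels = confusion_probs(tp=42, fn=8, tn=29, fp=12)
        rep = compute_metrics(probs, labels, "adaptive", prevalence=0.40)
        assert round(rep.accuracy, 3) == 0.780
        assert round(rep.sensitivity, 3) == 0.840
        assert round(rep.precision, 3) == 0.778
        assert round(rep.ppv_adj, 3) == 0.657
        assert round(rep.npv_adj, 3) == 0.869

    def test_wald_ci_worked_example(self):
        probs, labels = confusion_probs(tp=42, fn=8, tn=29, fp=12)
        rep = compute_metrics(probs, labels, "adaptive")
        lo, hi = rep.wald_cis["accuracy"]
        assert round(100 * lo, 1) == 69.5
        assert round(100 * hi, 1) == 86.5

    def test_perfect_predictions(self):
        probs, labels = confusion_probs(tp=10, fn=0, tn=8, fp=0)
        for pi in (0.1, 0.4, 0.9):
            rep = compute_metrics(probs, labels, "adaptive", prevalence=pi)
            assert rep.auc == 1.0
            assert rep.accuracy == rep.precision == rep.sensitivity == 1.0
            assert rep.ppv_adj == 1.0 and rep.npv_adj == 1.0

    def test_bayes_identity_ppv_at_sample_prevalence_equals_precision(self, rng):
        for _ in range(5):
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            probs = np.clip(0.5 * y + rng.normal(0.25, 0.2, 40), 0, 1)
            labels = np.where(y == 1, "adaptive", "non-adaptive").astype(object)
            rep = compute_metrics(probs, labels, "adaptive", prevalence=y.mean())
            if rep.tp + rep.fp > 0 and rep.specificity < 1:
                assert np.isclose(rep.ppv_adj, rep.precision, atol=1e-10)

    def test_auc_matches_sklearn_with_ties(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            scores = rng.integers(0, 5, 30) / 4.0  # plenty of ties
            assert np.isclose(auc_trapezoidal(y == 1, scores),
                              roc_auc_score(y, scores), atol=1e-12)

    def test_random_predictor_auc_near_half(self):
        aucs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            y = np.array([1, 0] * 25)
            probs = rng.random(50)
            labels = np.where(y == 1, "adaptive", "non-adaptive").astype(object)
            aucs.append(compute_metrics(probs, labels, "adaptive").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_metrics_invariant_under_row_permutation(self, rng):
        probs, labels = confusion_probs(tp=12, fn=5, tn=9, fp=4)
        probs = probs + rng.uniform(-0.05, 0.05, probs.size)
        rep1 = compute_metrics(probs, labels, "adaptive")
        perm = rng.permutation(probs.size)
        rep2 = compute_metrics(probs[perm], labels[perm], "adaptive")
        for attr in ("auc", "accuracy", "precision", "sensitivity",
                     "specificity", "ppv_adj", "npv_adj"):
            assert np.isclose(getattr(rep1, attr), getattr(rep2, attr))

    def test_invalid_inputs_rejected(self):
        probs, labels = confusion_probs(tp=5, fn=1, tn=4, fp=2)
        with pytest.raises(InputError):
            compute_metrics(probs, labels, "adaptive", prevalence=1.5)
        with pytest.raises(InputError):
            compute_metrics(probs, np.array(["adaptive"] * probs.size, dtype=object),
                            "adaptive")

    def test_confusion_identities(self):
        probs, labels = confusion_probs(tp=12, fn=5, tn=9, fp=4)
        rep = compute_metrics(probs, labels, "adaptive")
        n = probs.size
        assert rep.tp + rep.fn == 17 and rep.tn + rep.fp == 13
        assert np.isclose(rep.accuracy, (rep.tp + rep.tn) / n)
        assert np.isclose(rep.loo_error, 1 - rep.accuracy)


class TestLooPredict:
    def test_separated_clusters_classified_correctly(self):
        table, y = two_cluster_table(n=14, seed=1)
        probs = loo_predict(table, ["f0"], RFParams(n_trees=60, seed=1))
        assert ((probs >= 0.5) == (y == 1)).all()

    def test_minimal_three_row_table(self):
        table, _ = two_cluster_table(n=3, seed=2)
        probs = loo_predict(table, ["f0", "f1"], RFParams(n_trees=20, seed=2))
        assert probs.shape == (3,)
        assert ((0 <= probs) & (probs <= 1)).all()

    def test_unknown_signature_name_rejected(self):
        table, _ = two_cluster_table(n=8, seed=3)
        with pytest.raises(InputError):
            loo_predict(table, ["not_a_feature"], RFParams(n_trees=10))

    def test_label_permutation_destroys_signal(self):
        table, _ = two_cluster_table(n=24, seed=4)
        rng = np.random.default_rng(4)
        table.labels = table.labels[rng.permutation(table.n)]
        probs = loo_predict(table, ["f0", "f1", "f2"], RFParams(n_trees=60, seed=4))
        rep = compute_metrics(probs, table.labels, "adaptive")
        assert 0.3 <= rep.auc <= 0.7

    def test_deterministic_given_seed(self):
        table, _ = two_cluster_table(n=10, seed=5)
        a = loo_predict(table, ["f0", "f1"], RFParams(n_trees=30, seed=5))
        b = loo_predict(table, ["f0", "f1"], RFParams(n_trees=30, seed=5))
        np.testing.assert_array_equal(a, b)


class TestRFParams:
    def test_m_strictly_below_p_enforced(self):
        with pytest.raises(InputError):
            RFParams(max_features=3).resolve_m(3)
        assert RFParams(max_features=2).resolve_m(3) == 2
        assert RFParams().resolve_m(251) == 15


class TestBootstrap632Plus:
    def test_combination_rule_r_zero_reduces_to_632_estimator(self):
        # eps0 == err_bar -> R = 0, w = 0.632
        val = b632plus_from_components(err_bar=0.2, eps0=0.2, gamma=0.5)
        assert np.isclose(val, (1 - 0.632) * 0.2 + 0.632 * 0.2)

    def test_combination_rule_full_overfit_limit(self):
        # err_bar = 0 and eps0 = gamma -> R = 1, w = 0.632/(1-0.368) = 1: estimate = gamma
        val = b632plus_from_components(err_bar=0.0, eps0=0.5, gamma=0.5)
        assert np.isclose(val, b632plus_brute(0.0, 0.5, 0.5))
        assert np.isclose(val, 0.5)

    def test_formula_matches_independent_implementation(self, rng):
        for _ in range(20):
            err_bar = rng.uniform(0, 0.5)
            eps0 = rng.uniform(0, 0.7)
            gamma = rng.uniform(0.1, 0.6)
            assert np.isclose(b632plus_from_components(err_bar, eps0, gamma),
                              b632plus_brute(err_bar, eps0, gamma), atol=1e-12)

    def test_well_separated_table_has_low_632plus_error(self):
        table, _ = two_cluster_table(n=20, sep=8.0, seed=6)
        res = bootstrap_632plus(table, ["f0", "f1"], RFParams(n_trees=40, seed=6), B=30)
        assert res.value < 0.1

    def test_resubstitution_optimism_on_separable_data(self):
        wins = 0
        for s in range(10):
            table, _ = two_cluster_table(n=16, sep=2.0, seed=20 + s)
            res = bootstrap_632plus(table, ["f0", "f1", "f2"],
                                    RFParams(n_trees=30, seed=s), B=25)
            wins += res.err_bar <= res.eps0
        assert wins >= 8

    def test_b_below_two_rejected(self):
        table, _ = two_cluster_table(n=10, seed=7)
        with pytest.raises(InputError):
            bootstrap_632plus(table, ["f0"], RFParams(n_trees=10), B=1)
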
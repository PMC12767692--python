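"""Supervised models, permutation Shapley estimator, effect aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from sourcesig.causal_attribution import (
    ModelConfig,
    aggregate_effects,
    compare_models,
    expression_vs_attribution_report,
    paired_auc_summary,
    predict_proba_fn,
    shapley_values,
    train_model,
)


class TestTrainModel:
    def test_separable_data_perfect_training_auc(self):
        X = np.vstack([np.random.default_rng(0).normal(-3, 0.1, (50, 2)),
                       np.random.default_rng(1).normal(3, 0.1, (50, 2))])
        y = np.repeat([0, 1], 50)
        model = train_model(ModelConfig("random_forest", "sources", grid={}), X, y)
        assert roc_auc_score(y, model.predict_proba(X)[:, 1]) == 1.0

    def test_label_permutation_null_auc(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 5))
        y = rng.integers(0, 2, size=400)  # labels independent of features
        model = train_model(ModelConfig("elastic_net_logistic", "sources", grid={}), X[:300], y[:300])
        auc = roc_auc_score(y[300:], model.predict_proba(X[300:])[:, 1])
        assert abs(auc - 0.5) < 0.12

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] + rng.normal(0, 0.5, 200) > 0).astype(int)
        p1 = train_model(ModelConfig("gradient_boosted_trees", "sources", grid={}, seed=9), X, y).predict_proba(X)
        p2 = train_model(ModelConfig("gradient_boosted_trees", "sources", grid={}, seed=9), X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_model(ModelConfig("random_forest", "sources", grid={}), np.zeros((10, 2)), np.zeros(10))

    @pytest.mark.parametrize("arch", ["random_forest", "gradient_boosted_trees", "elastic_net_logistic"])
    def test_cv_grid_search_runs(self, arch):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 3))
        y = (X[:, 0] > 0).astype(int)
        model = train_model(ModelConfig(arch, "sources", grid=None, cv_folds=2), X, y)
        assert model.predict_proba(X).shape == (150, 2)


class TestShapley:
    def test_linear_model_closed_form(self):
        """For additive f(x) = w.x, phi_i = w_i (x_i - mean_i(background)),
        exactly, for any number of permutations."""
        rng = np.random.default_rng(5)
        w = np.array([2.0, -1.0, 0.5, 3.0])
        X = rng.normal(size=(15, 4))
        bg = rng.normal(size=(60, 4))
        expl = shapley_values(lambda Z: Z @ w, X, bg, n_permutations=4, seed=6)
        assert np.abs(expl.values - w * (X - bg.mean(0))).max() < 1e-10

    def test_efficiency_identity_every_sample(self):
        rng = np.random.default_rng(7)
        f = lambda Z: np.tanh(Z[:, 0] * Z[:, 1]) + Z[:, 2] ** 2
        expl = shapley_values(f, rng.normal(size=(25, 3)), rng.normal(size=(40, 3)),
                              n_permutations=5, seed=8)
        assert np.abs(expl.efficiency_gap()).max() < 1e-10

    def test_duplicate_features_equal_attribution(self):
        """Exact enumeration oracle at d=3: symmetric features get equal
        Shapley values; the Monte-Carlo estimate converges to it."""
        bg = np.zeros((1, 3))
        f = lambda Z: Z[:, 0] * Z[:, 1] + Z[:, 2]  # features 0 and 1 symmetric
        x = np.array([[2.0, 2.0, 1.0]])

        def exact_phi(i):
            total = 0.0
            for perm in itertools.permutations(range(3)):
                on = set()
                for j in perm:
                    before = f(np.where([k in on for k in range(3)], x, bg))[0]
                    on.add(j)
                    after = f(np.where([k in on for k in range(3)], x, bg))[0]
                    if j == i:
                        total += after - before
            return total / 6.0

        expl = shapley_values(f, x, bg, n_permutations=600, seed=9)
        for i in range(3):
            assert expl.values[0, i] == pytest.approx(exact_phi(i), abs=0.05)
        assert exact_phi(0) == pytest.approx(exact_phi(1))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            shapley_values(lambda Z: Z[:, 0], np.zeros((2, 2)), np.zeros((0, 2)))


class TestAggregateEffects:
    def test_polarity_means(self):
        values = np.array([[0.1], [-0.2], [0.3]])  # one feature, three samples
        t = aggregate_effects(type("E", (), {"values": values})()).table
        assert t.loc[0, "mean_positive_effect"] == pytest.approx(0.2)
        assert t.loc[0, "mean_negative_effect"] == pytest.approx(-0.2)

    def test_all_zero_attributions(self):
        t = aggregate_effects(type("E", (), {"values": np.zeros((5, 3))})()).table
        assert np.all(t["mean_positive_effect"] == 0.0)
        assert np.all(t["mean_negative_effect"] == 0.0)

    def test_ranks_are_permutations(self):
        rng = np.random.default_rng(10)
        t = aggregate_effects(type("E", (), {"values": rng.normal(size=(50, 6))})()).table
        assert sorted(t["rank_malignant"]) == list(range(1, 7))
        assert sorted(t["rank_benign"]) == list(range(1, 7))

    def test_scaling_invariance(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(30, 4))
        t1 = aggregate_effects(type("E", (), {"values": vals})()).table
        t2 = aggregate_effects(type("E", (), {"values": 3.0 * vals})()).table
        assert np.allclose(t2["mean_positive_effect"], 3.0 * t1["mean_positive_effect"])
        assert list(t1["rank_malignant"]) == list(t2["rank_malignant"])


@pytest.fixture(scope="module")
def toy_problem():
    rng = np.random.default_rng(12)
    S = rng.laplace(size=(600, 4))
    y = (S[:, 0] + 0.5 * S[:, 1] + rng.normal(0, 0.5, 600) > 0).astype(int)
    X = S @ rng.normal(size=(4, 10))  # entangled copies of the sources
    return S, X, y


class TestCompareModels:
    def test_identical_features_paired_difference_zero(self, toy_problem):
        S, _, y = toy_problem
        configs = [ModelConfig("random_forest", sp, grid={}) for sp in ("sources", "variables")]
        comp = compare_models(
            configs,
            {"sources": (S[:400], S[400:]), "variables": (S[:400], S[400:])},
            (y[:400], y[400:]),
            n_seeds=3,
        )
        summary = paired_auc_summary(comp)
        assert abs(summary["mean_difference"].iloc[0]) < 1e-12

    def test_single_seed_table_well_formed(self, toy_problem):
        S, X, y = toy_problem
        comp = compare_models(
            [ModelConfig("elastic_net_logistic", "sources", grid={})],
            {"sources": (S[:400], S[400:])},
            (y[:400], y[400:]),
            n_seeds=1,
        )
        assert list(comp.columns) == ["architecture", "input_space", "seed", "auc"]
        assert len(comp) == 1


class TestExpressionAttributionReport:
    def test_bin_counts_conserved(self):
        rng = np.random.default_rng(13)
        expr = rng.normal(size=300)
        points, curve = expression_vs_attribution_report(expr, rng.normal(size=300),
                                                        rng.integers(0, 2, 300))
        assert curve["n"].sum() == 300
        assert len(points) == 300

    def test_constant_outcome_flat_curve(self):
        rng = np.random.default_rng(14)
        _, curve = expression_vs_attribution_report(
            rng.normal(size=100), rng.normal(size=100), np.ones(100, dtype=int)
        )
        assert np.all(curve["probability"] == 1.0)

    def test_negative_enriched_outcomes_decreasing_trend(self):
        rng = np.random.default_rng(15)
        expr = rng.normal(size=2000)
        prob = 1 / (1 + np.exp(4 * expr))  # outcome concentrated at negative expression
        outcome = (rng.random(2000) < prob).astype(int)
        _, curve = expression_vs_attribution_report(expr, np.zeros(2000), outcome, n_bins=8)
        # monotone-decreasing trend test via rank correlation
        from scipy.stats import spearmanr

        rho, _ = spearmanr(curve["bin_center"], curve["probability"])
        assert rho < -0.8
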
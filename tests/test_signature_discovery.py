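"""PCA whitening, fixed-point ICA, sign/scale conventions, pruning."""

import numpy as np
import pytest

from sourcesig import synthetic_ehr as se
from sourcesig.cross_sections import fit_standardizer
from sourcesig.signature_discovery import (
    SignatureModel,
    back_transform_effects,
    fastica_fit,
    fastica_rotation,
    fit_pca_whitening,
    infer_expressions,
    orient_signs,
    prune_signature,
    scale_expressions,
)


@pytest.fixture(scope="module")
def fitted():
    """Standardized synthetic matrix with a fully fitted, oriented, scaled model."""
    gt = se.sample_ground_truth(20, 4, sparsity=0.5, seed=100)
    X, S_true = se.sample_cross_sections(gt, 8000, noise_sd=0.05, rng=np.random.default_rng(101))
    std = fit_standardizer(X)
    X_std = std.apply(X)
    model = fastica_fit(X_std, 4, seed=102, standardizer=std)
    raw = model.raw_expressions(X_std)
    model, raw = orient_signs(model, raw)
    S = scale_expressions(model, raw)
    return gt, X_std, S_true, model, S


class TestWhitening:
    def test_whitened_covariance_identity(self, rng):
        X = rng.normal(size=(10, 2000)) * rng.uniform(1, 10, size=(10, 1))
        pca, Z = fit_pca_whitening(X, 10)
        cov = Z @ Z.T / Z.shape[1]
        assert np.abs(cov - np.eye(10)).max() < 1e-6

    def test_full_rank_lossless(self, rng):
        X = rng.normal(size=(6, 500))
        pca, Z = fit_pca_whitening(X, 6)
        assert np.linalg.norm(pca.unwhiten(Z) - X) / np.linalg.norm(X) < 1e-9

    def test_retained_variance_nonincreasing_in_truncation(self, rng):
        X = rng.normal(size=(8, 1000)) * np.arange(1, 9)[:, None]
        # oracle: full eigendecomposition of the covariance
        Xc = X - X.mean(axis=1, keepdims=True)
        eig = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / X.shape[1]))[::-1]
        resid = []
        for m in (2, 4, 6, 8):
            pca, Z = fit_pca_whitening(X, m)
            retained = (pca.component_sd**2).sum()
            assert retained == pytest.approx(eig[:m].sum(), rel=1e-9)
            resid.append(eig.sum() - retained)
        assert all(a >= b - 1e-12 for a, b in zip(resid, resid[1:]))

    def test_m_beyond_rank_names_achievable_rank(self):
        X = np.vstack([np.arange(100.0), 2 * np.arange(100.0), np.ones(100)])
        with pytest.raises(ValueError, match="rank"):
            fit_pca_whitening(X, 3)


class TestFastICA:
    def test_two_laplace_sources_recovered(self):
        """Known 2x2 mixing, 50k samples: matched |r| >= 0.99 per source."""
        rng = np.random.default_rng(200)
        S_true = rng.laplace(size=(2, 50000))
        A_true = np.array([[1.0, 0.7], [0.3, -1.2]])
        X = A_true @ S_true
        model = fastica_fit(fit_standardizer(X).apply(X), 2, seed=201)
        S_est = model.raw_expressions(fit_standardizer(X).apply(X))
        C = np.abs(np.corrcoef(S_true, S_est)[:2, 2:])
        best = np.sort(C.max(axis=1))
        assert np.all(best >= 0.99)

    def test_rotation_orthonormal_even_for_gaussian_input(self):
        # Gaussian input cannot be separated; the contract is orthonormality only
        Z = np.random.default_rng(202).normal(size=(3, 5000))
        pca, Zw = fit_pca_whitening(Z, 3)
        W, _, _ = fastica_rotation(Zw, seed=203, max_iter=200)
        assert np.abs(W @ W.T - np.eye(3)).max() < 1e-6

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(204)
        X = rng.laplace(size=(4, 3000))
        Xs = fit_standardizer(X).apply(X)
        m1 = fastica_fit(Xs, 4, seed=205)
        m2 = fastica_fit(Xs, 4, seed=205)
        assert np.array_equal(m1.mixing, m2.mixing)

    def test_unmixing_is_left_inverse_of_mixing(self, fitted):
        _, _, _, model, _ = fitted
        assert np.abs(model.unmixing @ model.mixing - np.eye(model.m)).max() < 1e-6

    def test_reconstruction_within_pca_residual(self, fitted):
        _, X_std, _, model, _ = fitted
        raw = model.raw_expressions(X_std)
        rel = np.linalg.norm(X_std - model.reconstruct(raw)) / np.linalg.norm(X_std)
        Xc = X_std - X_std.mean(axis=1, keepdims=True)
        s = np.linalg.svd(Xc, compute_uv=False)
        pca_resid = np.sqrt((s[model.m:] ** 2).sum() / (s**2).sum())
        assert rel <= pca_resid + 1e-6


class TestSignOrientation:
    def test_dominant_elements_positive(self, fitted):
        _, _, _, model, _ = fitted
        A = model.mixing
        dom = np.argmax(np.abs(A), axis=0)
        assert np.all(A[dom, np.arange(model.m)] > 0)

    def test_flip_negates_column_and_expressions(self):
        rng = np.random.default_rng(300)
        X = rng.laplace(size=(6, 4000))
        Xs = fit_standardizer(X).apply(X)
        model = fastica_fit(Xs, 3, seed=301)
        raw = model.raw_expressions(Xs)
        A_before = model.mixing.copy()
        model, raw_after = orient_signs(model, raw)
        flips = np.array(
            [1.0 if np.allclose(model.mixing[:, j], A_before[:, j]) else -1.0 for j in range(3)]
        )
        assert np.allclose(model.mixing, A_before * flips)
        assert np.allclose(raw_after, raw * flips[:, None])

    def test_reconstruction_invariant(self):
        rng = np.random.default_rng(302)
        X = rng.laplace(size=(6, 4000))
        Xs = fit_standardizer(X).apply(X)
        model = fastica_fit(Xs, 3, seed=303)
        raw = model.raw_expressions(Xs)
        before = model.reconstruct(raw)
        model, raw = orient_signs(model, raw)
        assert np.abs(model.reconstruct(raw) - before).max() < 1e-9


class TestExpressionScaling:
    def test_mean_zero_sd_half(self, fitted):
        _, _, _, _, S = fitted
        assert np.abs(S.mean(axis=1)).max() < 1e-6
        assert np.abs(S.std(axis=1) - 0.5).max() < 1e-6

    def test_guarded_against_double_scaling(self, fitted):
        _, X_std, _, model, _ = fitted
        with pytest.raises(RuntimeError):
            scale_expressions(model, model.raw_expressions(X_std))

    def test_gaussian_sources_95pct_within_unit_interval(self):
        # with SD 0.5, Gaussian expressions put ~95% of mass in [-1, 1]
        z = np.random.default_rng(400).normal(0.0, 0.5, size=200000)
        frac = np.mean(np.abs(z) <= 1.0)
        assert frac == pytest.approx(0.9545, abs=0.005)


class TestInference:
    def test_discovery_round_trip(self, fitted):
        _, X_std, _, model, S = fitted
        assert np.abs(infer_expressions(model, X_std) - S).max() < 1e-6

    def test_scaled_signature_column_gives_unit_impulse(self, fitted):
        _, _, _, model, _ = fitted
        j = 1
        # input lying exactly along signature j at raw amplitude 1
        x = model.mixing[:, [j]] + model.pca.mean[:, None]
        s = infer_expressions(model, x)[:, 0]
        raw = (s / model.source_scale) + model.source_center
        expected = np.zeros(model.m)
        expected[j] = 1.0
        assert np.abs(raw - expected).max() < 1e-8

    def test_dimension_mismatch_raises(self, fitted):
        _, _, _, model, _ = fitted
        with pytest.raises(ValueError):
            infer_expressions(model, np.zeros((7, 3)))

    def test_partial_match_without_dominant_elements_is_nonzero(self, fitted):
        """A record matching a signature minus its dominant elements still
        expresses the source at a nonzero (often negative) level —
        characterization of the dense inverse mapping."""
        _, _, _, model, _ = fitted
        j = 0
        col = model.mixing[:, j].copy()
        k = np.argsort(-np.abs(col))[:3]
        col[k] = 0.0  # remove the dominant elements
        s = infer_expressions(model, col[:, None] + model.pca.mean[:, None])[:, 0]
        raw_j = s[j] / model.source_scale[j] + model.source_center[j]
        assert abs(raw_j - 1.0) > 0.05  # no longer a clean unit impulse
        assert abs(raw_j) > 1e-6


class TestPruning:
    def test_single_nonzero_k1(self):
        view = prune_signature(np.array([0.0, 2.5, 0.0]))
        assert view.k_top == 1

    def test_hand_computed_three_four_zero(self):
        # |.| sorted (4,3,0): top-1 ratio 0.8 < 0.975; top-2 ratio 1.0 -> k=2
        view = prune_signature(np.array([3.0, 4.0, 0.0]))
        assert view.k_top == 2
        assert view.cumulative_fraction[0] == pytest.approx(0.8)
        assert view.cumulative_fraction[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [5, 40, 1000])
    def test_equal_magnitudes_closed_form(self, n):
        view = prune_signature(np.ones(n))
        assert view.k_top == int(np.ceil(0.975**2 * n))

    def test_k_monotone_in_threshold(self, rng):
        col = rng.normal(size=50)
        ks = [prune_signature(col, threshold=t).k_top for t in (0.5, 0.8, 0.95, 0.99)]
        assert ks == sorted(ks)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            prune_signature(np.zeros(4))


class TestBackTransform:
    def test_operators_and_magnitudes(self, small_catalog, small_cohort):
        from sourcesig.cross_sections import Standardizer

        n = len(small_catalog)
        std = Standardizer(center=np.zeros(n), scale=np.full(n, 2.0), degenerate=np.zeros(n, bool))
        col = np.zeros(n)
        i_lab = small_catalog.index_of("lab:glucose")
        i_code = small_catalog.index_of("code:copd")
        col[i_lab] = 1.5
        col[i_code] = np.log(2.0) / 2.0  # weight * scale = log 2 -> factor 2
        view = prune_signature(col, small_catalog.variable_ids)
        view = back_transform_effects(view, std, small_catalog)
        effects = dict(zip(view.variable_ids, view.effects))
        op, val = effects["lab:glucose"]
        assert op == "+" and val == pytest.approx(3.0)  # 1.5 * scale 2
        op, val = effects["code:copd"]
        assert op == "x" and val == pytest.approx(2.0)

    def test_zero_code_weight_factor_one(self, small_catalog):
        from sourcesig.cross_sections import Standardizer

        n = len(small_catalog)
        std = Standardizer(center=np.zeros(n), scale=np.ones(n), degenerate=np.zeros(n, bool))
        col = np.zeros(n)
        col[small_catalog.index_of("code:copd")] = 1e-15
        view = back_transform_effects(prune_signature(col, small_catalog.variable_ids), std, small_catalog)
        op, val = view.effects[0]
        assert val == pytest.approx(1.0)


class TestSklearnCrossCheck:
    def test_matches_sklearn_fastica_subspace(self):
        """Independent oracle: sklearn FastICA recovers the same sources
        (up to permutation/sign) on a shared synthetic problem."""
        from sklearn.decomposition import FastICA

        rng = np.random.default_rng(500)
        S_true = rng.laplace(size=(3, 20000))
        A_true = rng.normal(size=(6, 3))
        X = A_true @ S_true
        Xs = fit_standardizer(X).apply(X)
        ours = fastica_fit(Xs, 3, seed=501)
        S_ours = ours.raw_expressions(Xs)
        sk = FastICA(n_components=3, whiten="unit-variance", random_state=501, max_iter=1000)
        S_sk = sk.fit_transform(Xs.T).T
        C = np.abs(np.corrcoef(S_ours, S_sk)[:3, 3:])
        # every one of our sources has an sklearn counterpart with |r| ~ 1
        assert np.all(C.max(axis=1) > 0.999)
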
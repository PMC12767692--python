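"""Latent-source discovery: PCA whitening + fixed-point ICA, X = A S.

The standardized cross-section matrix is reduced and whitened by PCA to ``m``
components, then rotated by symmetric (parallel) fixed-point ICA with the
logcosh contrast so that the recovered source expressions are maximally
non-Gaussian and mutually independent. The composed model exposes

* ``mixing`` A (n_vars x m): column j is source j's *signature*, the change
  in every standardized variable per unit expression of the source;
* ``unmixing`` U (m x n_vars): expressions = U @ (x - mean), the
  pseudo-inverse of A through the PCA subspace, with U A = I_m;
* per-source affine parameters scaling discovery-set expressions to mean 0
  and standard deviation 0.5 (the expression scale is not identifiable under
  ICA, so a convention is fixed once on the discovery cohort).

Sign convention: each signature is flipped so its dominant (largest |weight|)
element is a positive change; ties broken by lowest variable index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cross_sections import Standardizer
from .ehr_data import VariableCatalog

logger = logging.getLogger(__name__)

EXPRESSION_SD = 0.5


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PCAWhitening:
    """Rank-m PCA basis with whitening/unwhitening maps."""

    mean: np.ndarray  # (n_vars,)
    basis: np.ndarray  # (n_vars, m) orthonormal columns
    singular_values: np.ndarray  # (m,) of the centered data matrix
    n_samples: int

    @property
    def m(self) -> int:
        return self.basis.shape[1]

    @property
    def component_sd(self) -> np.ndarray:
        return self.singular_values / np.sqrt(self.n_samples)

    def whiten(self, X: np.ndarray) -> np.ndarray:
        """Project to m whitened components (identity covariance on fit data)."""
        return (self.basis.T @ (X - self.mean[:, None])) / self.component_sd[:, None]

    def unwhiten(self, Z: np.ndarray) -> np.ndarray:
        return self.basis @ (Z * self.component_sd[:, None]) + self.mean[:, None]


def fit_pca_whitening(X_std: np.ndarray, m: int) -> tuple[PCAWhitening, np.ndarray]:
    """Center, reduce to the top m principal components, and whiten.

    Returns the fitted basis and the whitened data (m x t). Raises if ``m``
    exceeds the achievable rank, naming it.
    """
    n, t = X_std.shape
    if m > min(n, t):
        raise ValueError(f"m={m} exceeds min(n_vars, t_samples)={min(n, t)}")
    mean = X_std.mean(axis=1)
    Xc = X_std - mean[:, None]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, t) * np.finfo(float).eps)) if s.size else 0
    if m > rank:
        raise ValueError(f"m={m} exceeds achievable rank {rank}")
    pca = PCAWhitening(mean=mean, basis=U[:, :m], singular_values=s[:m], n_samples=t)
    return pca, pca.whiten(X_std)


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^{-1/2} W (symmetric orthonormalization)."""
    vals, vecs = np.linalg.eigh(W @ W.T)
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T @ W


def fastica_rotation(
    Z: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, int, bool]:
    """Symmetric fixed-point ICA rotation on whitened data (logcosh contrast).

    Returns (W, n_iter, converged) with W orthonormal (m x m); sources are
    ``W @ Z``. Non-convergence issues a warning and returns the partial
    result.
    """
    m, t = Z.shape
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.normal(size=(m, m)))
    converged = False
    for it in range(1, max_iter + 1):
        WZ = W @ Z
        g = np.tanh(WZ)
        g_prime = 1.0 - g**2
        W_new = _sym_decorrelate(g @ Z.T / t - g_prime.mean(axis=1)[:, None] * W)
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
        W = W_new
        if lim < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fixed-point ICA did not converge in {max_iter} iterations (lim={lim:.2e})",
            ConvergenceWarning,
        )
    return W, it, converged


@dataclass
class SignatureModel:
    """Composed standardization + whitening + ICA model with source affines."""

    pca: PCAWhitening
    rotation: np.ndarray  # (m, m) orthonormal ICA rotation in whitened space
    standardizer: Standardizer | None = None
    source_center: np.ndarray | None = None
    source_scale: np.ndarray | None = None  # multiplier mapping raw -> scaled
    scaled: bool = False
    n_iter: int = 0
    converged: bool = True

    @property
    def m(self) -> int:
        return self.rotation.shape[0]

    @property
    def mixing(self) -> np.ndarray:
        """A (n_vars x m): x_std - mean = A @ s_raw on the PCA subspace."""
        return self.pca.basis @ (self.pca.component_sd[:, None] * self.rotation.T)

    @property
    def unmixing(self) -> np.ndarray:
        """U (m x n_vars): s_raw = U @ (x_std - mean); U @ A = I."""
        return (self.rotation / self.pca.component_sd[None, :]) @ self.pca.basis.T

    def raw_expressions(self, X_std: np.ndarray) -> np.ndarray:
        return self.unmixing @ (X_std - self.pca.mean[:, None])

    def reconstruct(self, S_raw: np.ndarray) -> np.ndarray:
        return self.mixing @ S_raw + self.pca.mean[:, None]


def fastica_fit(
    X_std: np.ndarray,
    m: int,
    tol: float = 1e-4,
    max_iter: int = 500,
    seed: int = 0,
    standardizer: Standardizer | None = None,
) -> SignatureModel:
    """Fit the full decomposition X_std ~ A S on a standardized matrix."""
    pca, Z = fit_pca_whitening(X_std, m)
    W, n_iter, ok = fastica_rotation(Z, tol=tol, max_iter=max_iter, seed=seed)
    return SignatureModel(
        pca=pca, rotation=W, standardizer=standardizer, n_iter=n_iter, converged=ok
    )


def orient_signs(model: SignatureModel, expressions: np.ndarray | None = None):
    """Flip each source so the dominant signature element is a positive change.

    Negating a mixing column and its expression row together leaves the
    reconstruction X = A S unchanged. Ties on |weight| break toward the
    lowest variable index (argmax's first-hit rule).
    """
    A = model.mixing
    dominant = np.argmax(np.abs(A), axis=0)
    flip = np.sign(A[dominant, np.arange(model.m)])
    flip[flip == 0] = 1.0
    model.rotation = model.rotation * flip[:, None]
    if model.source_center is not None:
        model.source_center = model.source_center * flip
    if expressions is not None:
        return model, expressions * flip[:, None]
    return model


def scale_expressions(model: SignatureModel, discovery_expressions: np.ndarray) -> np.ndarray:
    """Fix the per-source affine so discovery expressions have mean 0, SD 0.5.

    Guarded to run once; returns the scaled discovery expressions and stores
    the affine on the model for all future inference.
    """
    if model.scaled:
        raise RuntimeError("expressions already scaled; affine is fixed once")
    mu = discovery_expressions.mean(axis=1)
    sd = discovery_expressions.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("degenerate source with zero expression variance")
    model.source_center = mu
    model.source_scale = EXPRESSION_SD / sd
    model.scaled = True
    return (discovery_expressions - mu[:, None]) * model.source_scale[:, None]


def infer_expressions(model: SignatureModel, X_std: np.ndarray) -> np.ndarray:
    """Scaled source expressions for new standardized cross-sections."""
    if not model.scaled:
        raise RuntimeError("model must be scaled before inference")
    if X_std.shape[0] != model.pca.basis.shape[0]:
        raise ValueError(
            f"expected {model.pca.basis.shape[0]} variables, got {X_std.shape[0]}"
        )
    raw = model.raw_expressions(X_std)
    return (raw - model.source_center[:, None]) * model.source_scale[:, None]


# ---------------------------------------------------------------------------
# Signature rendering


@dataclass
class SignatureView:
    """Top-k display form of one signature, ordered by |weight| descending."""

    source_id: int
    variable_ids: list[str]
    weights: np.ndarray  # standardized-space weights, |w| descending
    cumulative_fraction: np.ndarray  # of the full column's L2 norm
    k_top: int
    effects: list[tuple[str, float]] = field(default_factory=list)  # (operator, value)


def prune_signature(
    column: np.ndarray,
    variable_ids: list[str] | None = None,
    source_id: int = 0,
    threshold: float = 0.975,
) -> SignatureView:
    """Smallest top-k subset holding >= threshold of the column's L2 norm."""
    column = np.asarray(column, dtype=float)
    total = np.linalg.norm(column)
    if total == 0:
        raise ValueError("all-zero signature column")
    order = np.argsort(-np.abs(column), kind="stable")
    cum = np.sqrt(np.cumsum(column[order] ** 2)) / total
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    if variable_ids is None:
        variable_ids = [str(i) for i in range(len(column))]
    return SignatureView(
        source_id=source_id,
        variable_ids=[variable_ids[i] for i in order],
        weights=column[order],
        cumulative_fraction=cum,
        k_top=k,
    )


def back_transform_effects(
    view: SignatureView, standardizer: Standardizer, catalog: VariableCatalog
) -> SignatureView:
    """Original-unit effect per variable.

    Lab/medication/demographic effects are additive (weight x variable scale,
    operators +/-); billing-code effects act on log intensity, so the
    original-unit effect is the multiplicative rate factor
    exp(weight x scale) (operators x and /).
    """
    effects = []
    for vid, w in zip(view.variable_ids, view.weights):
        sigma = standardizer.scale[catalog.index_of(vid)]
        if catalog.mode_of(vid) == "code":
            factor = float(np.exp(w * sigma))
            effects.append(("x" if factor >= 1.0 else "/", factor if factor >= 1.0 else 1.0 / factor))
        else:
            delta = float(w * sigma)
            effects.append(("+" if delta >= 0 else "-", abs(delta)))
    view.effects = effects
    return view
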
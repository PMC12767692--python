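"""Supervised outcome models and Shapley-value causal attribution.

Two families of classifiers are trained for the malignant/benign prediction:
*causal* models on latent source expressions (mutually independent root
nodes, so per-feature attributions read as patient-specific causal effects)
and *associational* baselines on the raw entangled variables. Per-sample
feature attributions are Shapley values estimated by Monte-Carlo permutation
sampling with marginal (interventional) expectations over a fixed background
sample; the estimator satisfies the efficiency identity exactly on every
sample by telescoping along each permutation.

Per-source causal effects aggregate attributions with a polarity convention:
the malignant-direction effect of a source is the mean over its strictly
positive per-sample attributions (negative values omitted), and the
benign-direction effect is the mean over strictly negative attributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.proportion import proportion_confint
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

Architecture = Literal["random_forest", "gradient_boosted_trees", "elastic_net_logistic"]
InputSpace = Literal["sources", "variables"]

DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {"max_features": ["sqrt", 1.0], "min_samples_leaf": [1, 5, 20]},
    "gradient_boosted_trees": {"max_depth": [2, 4], "learning_rate": [0.1, 0.3]},
    "elastic_net_logistic": {"clf__C": [0.1, 1.0, 10.0], "clf__l1_ratio": [0.2, 0.8]},
}


@dataclass(frozen=True)
class ModelConfig:
    """One of the six architecture x input-space configurations."""

    architecture: Architecture
    input_space: InputSpace
    grid: dict | None = None  # None -> DEFAULT_GRIDS; {} -> no CV search
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in DEFAULT_GRIDS:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.input_space not in ("sources", "variables"):
            raise ValueError(f"unknown input space {self.input_space!r}")


def _base_estimator(arch: Architecture, seed: int):
    if arch == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if arch == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegression(
                    solver="saga", l1_ratio=0.5, C=1.0, max_iter=5000, random_state=seed,
                ),
            ),
        ]
    )


def train_model(config: ModelConfig, features: np.ndarray, labels: np.ndarray):
    """Fit a probabilistic classifier, selecting hyperparameters by CV.

    Deterministic under ``config.seed``. Raises on single-class labels.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    est = _base_estimator(config.architecture, config.seed)
    grid = DEFAULT_GRIDS[config.architecture] if config.grid is None else config.grid
    if grid:
        search = GridSearchCV(est, grid, cv=config.cv_folds, scoring="roc_auc", n_jobs=1)
        search.fit(features, labels)
        logger.info("CV-selected %s params: %s", config.architecture, search.best_params_)
        return search.best_estimator_
    est.fit(features, labels)
    return est


# ---------------------------------------------------------------------------
# Shapley attribution


@dataclass
class ShapleyExplanation:
    """Per-sample, per-feature Shapley attributions with efficiency metadata."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float  # mean prediction over the background
    predictions: np.ndarray  # f(x) per explained sample
    n_permutations: int
    seed: int

    def efficiency_gap(self) -> np.ndarray:
        """f(x) - base - sum(attributions), per sample (0 up to float error)."""
        return self.predictions - self.base_value - self.values.sum(axis=1)


def shapley_values(
    predict: Callable[[np.ndarray], np.ndarray],
    samples: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 16,
    seed: int = 0,
) -> ShapleyExplanation:
    """Monte-Carlo permutation Shapley values with marginal expectations.

    For each sampled feature ordering, features are switched one at a time
    from background values to the explained sample's values; the increase in
    the background-averaged prediction is credited to the switched feature.
    Averaging over orderings estimates the Shapley value under the marginal
    (interventional) value function v(S) = E_b[f(x_S, b_{\\bar S})]. The sum
    of credits along any ordering telescopes to f(x) - E_b[f(b)], so the
    efficiency identity holds exactly for every sample.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n, d = samples.shape
    b = background.shape[0]
    rng = np.random.default_rng(seed)
    base = float(np.mean(predict(background)))
    phi = np.zeros((n, d))
    # z holds one hybrid row per (explained sample, background row)
    for _ in range(n_permutations):
        order = rng.permutation(d)
        z = np.broadcast_to(background, (n, b, d)).copy()
        prev = np.full(n, base)
        for j in order:
            z[:, :, j] = samples[:, None, j]
            cur = predict(z.reshape(n * b, d)).reshape(n, b).mean(axis=1)
            phi[:, j] += cur - prev
            prev = cur
    phi /= n_permutations
    return ShapleyExplanation(
        values=phi,
        base_value=base,
        predictions=np.asarray(predict(samples), dtype=float),
        n_permutations=n_permutations,
        seed=seed,
    )


def predict_proba_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    """Positive-class probability scorer for a fitted sklearn-style model."""
    return lambda X: model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class CausalEffectTable:
    """Per-source polarity-specific mean attributions and ranks."""

    table: pd.DataFrame  # source, mean_positive_effect, mean_negative_effect,
    #                      rank_malignant, rank_benign


def aggregate_effects(
    explanation: ShapleyExplanation, source_ids: Sequence | None = None
) -> CausalEffectTable:
    """Polarity-specific global mean attributions per source.

    The malignant-direction effect is the mean over strictly positive
    per-sample attributions (omitting negative values); the benign-direction
    effect the mean over strictly negative ones. Sources with no qualifying
    values get effect 0. Ranks order |effect| descending within each
    polarity, ties broken by source id.
    """
    vals = explanation.values
    m = vals.shape[1]
    if source_ids is None:
        source_ids = list(range(m))
    pos = np.array([vals[vals[:, i] > 0, i].mean() if (vals[:, i] > 0).any() else 0.0 for i in range(m)])
    neg = np.array([vals[vals[:, i] < 0, i].mean() if (vals[:, i] < 0).any() else 0.0 for i in range(m)])
    df = pd.DataFrame(
        {
            "source": list(source_ids),
            "mean_positive_effect": pos,
            "mean_negative_effect": neg,
        }
    )
    # rank by |effect| within polarity, ties by source id
    order_m = np.lexsort((df["source"].to_numpy(), -np.abs(pos)))
    order_b = np.lexsort((df["source"].to_numpy(), -np.abs(neg)))
    rank_m = np.empty(m, dtype=int)
    rank_b = np.empty(m, dtype=int)
    rank_m[order_m] = np.arange(1, m + 1)
    rank_b[order_b] = np.arange(1, m + 1)
    df["rank_malignant"] = rank_m
    df["rank_benign"] = rank_b
    return CausalEffectTable(df)


# ---------------------------------------------------------------------------
# Model comparison


def compare_models(
    configs: Sequence[ModelConfig],
    features_by_space: dict[str, tuple[np.ndarray, np.ndarray]],
    labels: tuple[np.ndarray, np.ndarray],
    n_seeds: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Repeat training across seeds on a fixed train/test split.

    ``features_by_space`` maps input space -> (train, test) feature matrices
    sharing the common (y_train, y_test). Hyperparameters are CV-selected
    once per configuration at the base seed, then held fixed while the seed
    varies. Returns a tidy frame (architecture, input_space, seed, auc).
    """
    y_train, y_test = labels
    rows = []
    for cfg in configs:
        X_train, X_test = features_by_space[cfg.input_space]
        tuned = train_model(cfg, X_train, y_train)
        params = tuned.get_params()
        for k in range(n_seeds):
            seed = base_seed + k
            est = _base_estimator(cfg.architecture, seed)
            keep = {
                name: val
                for name, val in params.items()
                if name in est.get_params()
                and "random_state" not in name
                and not hasattr(val, "get_params")  # don't share nested estimator objects
                and name not in ("steps", "memory")
            }
            est.set_params(**keep)
            est.fit(X_train, y_train)
            auc = roc_auc_score(y_test, est.predict_proba(X_test)[:, 1])
            rows.append((cfg.architecture, cfg.input_space, seed, float(auc)))
    df = pd.DataFrame(rows, columns=["architecture", "input_space", "seed", "auc"])
    return df


def paired_auc_summary(comparison: pd.DataFrame) -> pd.DataFrame:
    """Seed-wise paired differences: causal (sources) minus associational."""
    wide = comparison.pivot_table(
        index=["architecture", "seed"], columns="input_space", values="auc"
    ).reset_index()
    wide["difference"] = wide["sources"] - wide["variables"]
    return (
        wide.groupby("architecture")
        .agg(
            mean_causal=("sources", "mean"),
            mean_associational=("variables", "mean"),
            mean_difference=("difference", "mean"),
            sd_difference=("difference", "std"),
        )
        .reset_index()
    )


def expression_vs_attribution_report(
    expressions: np.ndarray,
    attributions: np.ndarray,
    outcomes: np.ndarray,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter triples plus an expression-binned outcome-probability curve.

    Returns (points, curve): points holds the per-record (expression,
    attribution, outcome) triples; curve holds, per equal-width expression
    bin, the bin center, record count, empirical outcome probability and a
    95% Wilson confidence interval. Bin counts sum to the cohort size.
    """
    expressions = np.asarray(expressions, dtype=float)
    attributions = np.asarray(attributions, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    points = pd.DataFrame(
        {"expression": expressions, "attribution": attributions, "outcome": outcomes}
    )
    edges = np.linspace(expressions.min(), expressions.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, expressions, side="right") - 1, 0, n_bins - 1)
    rows = []
    for i in range(n_bins):
        mask = idx == i
        n = int(mask.sum())
        if n == 0:
            continue
        k = int(outcomes[mask].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(((edges[i] + edges[i + 1]) / 2, n, k / n, float(lo), float(hi)))
    curve = pd.DataFrame(rows, columns=["bin_center", "n", "probability", "ci_low", "ci_high"])
    return points, curve
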
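"""Synthetic EHR cohorts driven by a known latent-source ground truth.

The generator emulates the structure the discovery pipeline assumes: a sparse
linear mixing of mutually independent, non-Gaussian latent sources into a
latent per-variable profile, observed through sparse, irregular, asynchronous
per-mode processes (noisy lab draws, Poisson billing-code streams, Bernoulli
medication presence). Because the ground truth (mixing matrix, per-record
expressions, causal source set) is returned alongside the cohort, every
downstream stage can be scored against it.

Modeling choices (see docs/methods.md): active-source expressions follow a
Laplace law (super-Gaussian, satisfying ICA's non-Gaussianity requirement);
expressions are constant within a record; record spans are exponential;
the last two sources additionally drive sex and race so that demographic
signatures exist to recover; outcome labels follow a logistic model on the
designated causal sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ehr_data import (
    RACE_LEVELS,
    SEX_LEVELS,
    CodeEvent,
    Demographics,
    LabObservation,
    MedicationMention,
    PatientRecord,
)

DAYS_PER_YEAR = 365.25


@dataclass
class GroundTruth:
    """Known latent structure behind a synthetic cohort."""

    n_vars: int
    m_sources: int
    mixing_true: np.ndarray  # (n_vars, m_sources), unit-norm sparse columns
    source_sparsity: float = 0.5
    source_scale: float = 1.0
    causal_source_ids: tuple[int, ...] = ()
    outcome_weights: np.ndarray | None = None  # aligned with causal_source_ids

    def __post_init__(self) -> None:
        if self.m_sources < 2:
            raise ValueError("need at least 2 sources")
        if self.mixing_true.shape != (self.n_vars, self.m_sources):
            raise ValueError("mixing_true shape mismatch")
        if any(i < 0 or i >= self.m_sources for i in self.causal_source_ids):
            raise ValueError("causal_source_ids out of range")
        if self.outcome_weights is None:
            self.outcome_weights = np.full(len(self.causal_source_ids), 3.0)
        self.outcome_weights = np.asarray(self.outcome_weights, dtype=float)
        if len(self.outcome_weights) != len(self.causal_source_ids):
            raise ValueError("outcome_weights must align with causal_source_ids")


@dataclass
class SimConfig:
    """Observation-process parameters for cohort simulation."""

    n_records: int = 1000
    mean_span_years: float = 5.0
    lab_obs_rate: float = 4.0  # observations per variable-year
    code_base_rate: float = 2.0  # events per year at zero latent shift
    med_flip_prob: float = 0.1  # baseline medication presence probability
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_span_years", "lab_obs_rate", "code_base_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def sample_ground_truth(
    n_vars: int,
    m_sources: int,
    sparsity: float = 0.3,
    seed: int = 0,
    n_causal: int = 0,
    max_tries: int = 100,
) -> GroundTruth:
    """Draw a sparse unit-column mixing matrix with well-separated columns.

    Each column has an expected fraction ``sparsity`` of nonzero Gaussian
    loadings and unit Euclidean norm; columns with pairwise |cosine| >= 0.95
    are resampled (bounded retries). The first ``n_causal`` sources are
    designated causal for the outcome.
    """
    if not (n_vars >= m_sources >= 2):
        raise ValueError("need n_vars >= m_sources >= 2")
    rng = np.random.default_rng(seed)
    A = np.zeros((n_vars, m_sources))

    def draw_column() -> np.ndarray:
        for _ in range(max_tries):
            mask = rng.random(n_vars) < sparsity
            if mask.sum() == 0:
                continue
            col = np.where(mask, rng.normal(size=n_vars), 0.0)
            nrm = np.linalg.norm(col)
            if nrm > 0:
                return col / nrm
        raise RuntimeError("could not draw a nonzero column; sparsity too low")

    for j in range(m_sources):
        for _ in range(max_tries):
            col = draw_column()
            if j == 0 or np.max(np.abs(A[:, :j].T @ col)) < 0.95:
                A[:, j] = col
                break
        else:
            raise RuntimeError("could not find a sufficiently distinct column")
    return GroundTruth(
        n_vars=n_vars,
        m_sources=m_sources,
        mixing_true=A,
        causal_source_ids=tuple(range(n_causal)),
    )


def sample_expressions(gt: GroundTruth, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an (m_sources, n_samples) expression matrix.

    Each source is active independently with probability ``source_sparsity``;
    active values are Laplace(0, source_scale). Columns are i.i.d., rows are
    mutually independent by construction.
    """
    m = gt.m_sources
    active = rng.random((m, n_samples)) < gt.source_sparsity
    vals = rng.laplace(0.0, gt.source_scale, size=(m, n_samples))
    return np.where(active, vals, 0.0)


def sample_cross_sections(
    gt: GroundTruth,
    n_samples: int,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix-level benchmark data: X = A_true S + noise.

    Returns ``(X, S)`` with X of shape (n_vars, n_samples). This bypasses the
    event/curve observation layer and isolates decomposition recovery.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    S = sample_expressions(gt, n_samples, rng)
    X = gt.mixing_true @ S + rng.normal(0.0, noise_sd, size=(gt.n_vars, n_samples))
    return X, S


def outcome_probability(gt: GroundTruth, s: np.ndarray) -> np.ndarray:
    """P(label positive | expressions) under the logistic outcome model."""
    s = np.atleast_2d(s)  # (m, n)
    logit = gt.outcome_weights @ s[list(gt.causal_source_ids), :]
    return 1.0 / (1.0 + np.exp(-logit))


def _mode_split(n_vars: int) -> tuple[int, int, int]:
    """Partition variables into modes: roughly half labs, a third codes, rest meds."""
    if n_vars < 3:
        raise ValueError("record simulation needs at least 3 variables (one per mode)")
    n_lab = max(1, n_vars // 2)
    n_code = max(1, n_vars // 3)
    n_med = n_vars - n_lab - n_code
    if n_med < 1:
        n_code -= 1 - n_med
        n_med = 1
    return n_lab, n_code, n_med


def simulate_record(
    gt: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
    record_id: str = "r0",
    s: np.ndarray | None = None,
) -> tuple[PatientRecord, np.ndarray]:
    """Simulate one record; returns (record, true expression vector).

    The latent variable profile is ``x* = mixing_true @ s``. Per mode:

    * lab variable i: observation times from a Poisson process at
      ``lab_obs_rate``/yr, values = x*_i + Gaussian(0, noise_sd);
    * code variable i: Poisson event stream with rate
      ``code_base_rate * exp(x*_i)``/yr, times uniform over the span;
    * med variable i: present with prob sigmoid(logit(med_flip_prob) + x*_i),
      rendered as 1–3 mentions at random days;
    * demographics: the last two sources shift the log-odds of sex and the
      race-category scores, so demographic structure is source-driven.
    """
    if s is None:
        s = sample_expressions(gt, 1, rng)[:, 0]
    x_star = gt.mixing_true @ s
    span_days = float(
        np.clip(rng.exponential(cfg.mean_span_years * DAYS_PER_YEAR), 90.0, 40 * DAYS_PER_YEAR)
    )
    span_years = span_days / DAYS_PER_YEAR
    n_lab, n_code, n_med = _mode_split(gt.n_vars)

    labs = []
    for i in range(n_lab):
        k = rng.poisson(cfg.lab_obs_rate * span_years)
        days = np.sort(rng.uniform(0.0, span_days, size=k))
        for d in days:
            labs.append(
                LabObservation(f"t{i}", float(d), float(x_star[i] + rng.normal(0.0, cfg.noise_sd)))
            )
    codes = []
    for i in range(n_code):
        rate = cfg.code_base_rate * np.exp(np.clip(x_star[n_lab + i], -8.0, 8.0))
        k = rng.poisson(rate * span_years)
        for d in rng.uniform(0.0, span_days, size=k):
            codes.append(CodeEvent(f"c{i}", float(d)))
    meds = []
    base_logit = np.log(cfg.med_flip_prob / (1.0 - cfg.med_flip_prob))
    for i in range(n_med):
        p = 1.0 / (1.0 + np.exp(-(base_logit + x_star[n_lab + n_code + i])))
        if rng.random() < p:
            for d in rng.uniform(0.0, span_days, size=rng.integers(1, 4)):
                meds.append(MedicationMention(f"m{i}", float(d)))

    sex_logit = 2.0 * s[-1]
    sex = SEX_LEVELS[int(rng.random() < 1.0 / (1.0 + np.exp(-sex_logit)))]
    race_scores = np.array([0.0, s[-2], -s[-2]])
    race = RACE_LEVELS[int(np.argmax(race_scores + rng.gumbel(size=3)))]
    birth_offset = -float(rng.uniform(20, 80) * DAYS_PER_YEAR)
    record = PatientRecord(
        record_id=record_id,
        span_days=span_days,
        labs=labs,
        codes=codes,
        meds=meds,
        demographics=Demographics(sex, race, birth_offset),
        index_day=span_days,
    ).sorted()
    return record, s


def simulate_cohort(
    gt: GroundTruth, cfg: SimConfig
) -> tuple[list[PatientRecord], np.ndarray, np.ndarray]:
    """Simulate a cohort; returns (records, expressions (m, n), labels (n,)).

    Labels are Bernoulli(sigmoid(outcome_weights . s_causal)) and are also
    attached to each record. Fully deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    S = sample_expressions(gt, cfg.n_records, rng)
    p = outcome_probability(gt, S)
    labels = (rng.random(cfg.n_records) < p).astype(int)
    records = []
    for j in range(cfg.n_records):
        rec, _ = simulate_record(gt, cfg, rng, record_id=f"r{j:06d}", s=S[:, j])
        rec.label = "positive" if labels[j] else "negative"
        records.append(rec)
    return records, S, labels
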
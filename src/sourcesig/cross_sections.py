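"""Random cross-section sampling and the standardized data matrix.

Each record's curve set is sampled at uniformly random times at a mean density
of one sample per three record-years (so a record may be sampled once, many
times, or not at all, with longer records sampled more often). Cross-sections
are stacked column-wise into an ``n_vars x t_samples`` matrix, which is then
standardized per variable (zero mean, unit variance across samples) to put
all variables on roughly the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ehr_data import PatientRecord, VariableCatalog
from .longitudinal_curves import CurveSet

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DEFAULT_DENSITY_PER_YEAR = 1.0 / 3.0


@dataclass
class CrossSectionMatrix:
    """Variables-by-samples matrix with per-column provenance."""

    values: np.ndarray  # (n_vars, t_samples)
    variable_ids: list[str]
    provenance: pd.DataFrame  # columns: record_id, sample_day

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.provenance):
            raise ValueError("provenance length must equal sample count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cross-section matrix contains non-finite entries")


def sample_times(
    span_days: float,
    rng: np.random.Generator,
    mean_density_per_year: float = DEFAULT_DENSITY_PER_YEAR,
) -> np.ndarray:
    """Poisson(span_years * density) draws, i.i.d. uniform on [0, span]."""
    if span_days < 0:
        raise ValueError("span_days must be >= 0")
    n = rng.poisson(span_days / DAYS_PER_YEAR * mean_density_per_year)
    return np.sort(rng.uniform(0.0, span_days, size=n)) if n else np.empty(0)


def build_sampling_plan(
    records: Sequence[PatientRecord],
    rng: np.random.Generator,
    mean_density_per_year: float = DEFAULT_DENSITY_PER_YEAR,
) -> pd.DataFrame:
    """Randomized (record_id, sample_day) plan over a cohort."""
    rows = []
    for rec in records:
        for day in sample_times(rec.span_days, rng, mean_density_per_year):
            rows.append((rec.record_id, float(day)))
    return pd.DataFrame(rows, columns=["record_id", "sample_day"])


def index_day_plan(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Evaluation plan: one cross-section per record, at its index day."""
    rows = [(r.record_id, float(r.index_day)) for r in records if r.index_day is not None]
    return pd.DataFrame(rows, columns=["record_id", "sample_day"])


def assemble_matrix(
    curvesets: Mapping[str, CurveSet],
    plan: pd.DataFrame,
    catalog: VariableCatalog,
) -> CrossSectionMatrix:
    """Evaluate every variable's curve at each planned (record, day)."""
    cols = np.empty((len(catalog), len(plan)))
    for j, row in enumerate(plan.itertuples()):
        cols[:, j] = curvesets[str(row.record_id)].evaluate_at(row.sample_day, catalog)
    return CrossSectionMatrix(cols, catalog.variable_ids, plan.reset_index(drop=True))


@dataclass
class Standardizer:
    """Invertible per-variable affine map to zero mean / unit variance.

    Zero-variance variables keep scale 1 (centered only) and are flagged.
    """

    center: np.ndarray = field(default_factory=lambda: np.empty(0))
    scale: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def fit(self, X: np.ndarray) -> "Standardizer":
        if X.shape[1] < 2:
            raise ValueError("need at least 2 samples to fit a standardizer")
        self.center = X.mean(axis=1)
        sd = X.std(axis=1)
        self.degenerate = sd == 0
        if self.degenerate.any():
            logger.warning("%d zero-variance variables; scale set to 1", self.degenerate.sum())
        self.scale = np.where(self.degenerate, 1.0, sd)
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center[:, None]) / self.scale[:, None]

    def invert(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale[:, None] + self.center[:, None]

    def to_frame(self, variable_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable_id": list(variable_ids),
                "center": self.center,
                "scale": self.scale,
                "degenerate": self.degenerate,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Standardizer":
        return cls(
            center=df["center"].to_numpy(float),
            scale=df["scale"].to_numpy(float),
            degenerate=df["degenerate"].to_numpy(bool),
        )


def fit_standardizer(X: np.ndarray) -> Standardizer:
    return Standardizer().fit(X)
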
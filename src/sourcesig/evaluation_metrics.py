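"""Scoring discovered signatures against references and ground truth.

Three kinds of evaluation live here:

* **completeness / decomposition** against a curated reference list of
  nodule etiologies — completeness is the fraction of listed causes matched
  by at least one discovered signature; decomposition is the average number
  of matching signatures per matched cause. Both can count at per-row
  (element) or per-group granularity, because closely related rows (e.g. the
  four primary-lung-cancer cell types) may share one signature set.
* **evidence tally** over a ranked top-k list of inferred causes annotated
  with literature-evidence grades.
* **recovery score** against synthetic ground truth: optimal one-to-one
  matching (Hungarian method) of estimated to true source expressions by
  absolute correlation, which is invariant to ICA's permutation, sign and
  scale indeterminacies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

EVIDENCE_GRADES = ("Direct", "Strong", "Moderate", "Weak", "Mixed", "Absent")


# ---------------------------------------------------------------------------
# Reference list


@dataclass
class ReferenceList:
    """Curated etiology list with per-element matched signature ids.

    Columns: ``category`` (malignant/benign), ``element`` (unique within
    category), ``group_key`` (rows sharing a signature set), and
    ``signature_ids`` (semicolon-separated, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"category", "element", "group_key", "signature_ids"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reference list missing columns {sorted(missing)}")
        dup = self.table.duplicated(subset=["category", "element"])
        if dup.any():
            raise ValueError("element names must be unique within category")

    def category(self, category: str) -> pd.DataFrame:
        sub = self.table[self.table["category"] == category]
        if sub.empty:
            raise ValueError(f"no elements in category {category!r}")
        return sub

    @staticmethod
    def parse_ids(cell) -> set[str]:
        if pd.isna(cell) or str(cell).strip() == "":
            return set()
        return {tok.strip() for tok in str(cell).split(";") if tok.strip()}


def load_reference_list(path: str | Path) -> ReferenceList:
    return ReferenceList(pd.read_csv(path, dtype=str))


def _bundled(name: str) -> pd.DataFrame:
    with resources.files("sourcesig.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str)


def load_bundled_reference() -> ReferenceList:
    """Reference etiology list for indeterminate pulmonary nodules."""
    return ReferenceList(_bundled("reference_etiologies.csv"))


def load_bundled_top_causes(category: str) -> pd.DataFrame:
    """Published top-20 inferred causes (malignant or benign), ranked."""
    if category not in ("malignant", "benign"):
        raise ValueError("category must be 'malignant' or 'benign'")
    df = _bundled(f"top_causes_{category}.csv")
    df["mean_causal_effect"] = df["mean_causal_effect"].astype(float)
    df["rank"] = df["rank"].astype(int)
    return df.sort_values("rank").reset_index(drop=True)


def load_bundled_cohort_counts() -> pd.DataFrame:
    """Published cohort record counts per set and label stratum."""
    df = _bundled("cohort_counts.csv")
    df["n_records"] = df["n_records"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Completeness / decomposition


def _grouped_ids(ref: ReferenceList, category: str, granularity: str) -> list[set[str]]:
    sub = ref.category(category)
    if granularity == "element":
        return [ReferenceList.parse_ids(c) for c in sub["signature_ids"]]
    if granularity == "group":
        out = []
        for _, g in sub.groupby("group_key", sort=False):
            ids: set[str] = set()
            for c in g["signature_ids"]:
                ids |= ReferenceList.parse_ids(c)
            out.append(ids)
        return out
    raise ValueError("granularity must be 'element' or 'group'")


def completeness(ref: ReferenceList, category: str, granularity: str = "element") -> float:
    """Fraction of listed causes matched by at least one signature."""
    units = _grouped_ids(ref, category, granularity)
    return sum(bool(u) for u in units) / len(units)


def decomposition(ref: ReferenceList, category: str, granularity: str = "element") -> float:
    """Mean matched-signature count over matched causes (full precision)."""
    units = [u for u in _grouped_ids(ref, category, granularity) if u]
    if not units:
        raise ValueError(f"no matched elements in category {category!r}")
    return float(np.mean([len(u) for u in units]))


def display_decomposition(value: float) -> float:
    """One-decimal display rounding toward zero (5.55... -> 5.5)."""
    return math.floor(value * 10) / 10 if value >= 0 else math.ceil(value * 10) / 10


def match_table(ref: ReferenceList, category: str) -> pd.DataFrame:
    """Per-element matched-signature counts for one category."""
    sub = ref.category(category).copy()
    sub["n_signatures"] = [len(ReferenceList.parse_ids(c)) for c in sub["signature_ids"]]
    sub["matched"] = sub["n_signatures"] > 0
    return sub[["category", "element", "group_key", "n_signatures", "matched"]]


# ---------------------------------------------------------------------------
# Evidence tally


def tally_evidence(ranked: pd.DataFrame, top_k: int = 20) -> dict[str, int]:
    """Evidence-grade counts among the top-k ranked inferred causes.

    ``ranked`` needs an ``evidence`` column ordered best-first (or a ``rank``
    column to sort by). Compound grades count toward each named grade, and
    ``direct`` counts any grade string containing "Direct".
    """
    if top_k > len(ranked):
        raise ValueError(f"top_k={top_k} exceeds list length {len(ranked)}")
    df = ranked.sort_values("rank").head(top_k) if "rank" in ranked.columns else ranked.head(top_k)
    grades = df["evidence"].astype(str)
    counts = {g.lower(): int(grades.str.contains(g, case=True).sum()) for g in EVIDENCE_GRADES}
    counts["direct"] = int(grades.str.contains("Direct").sum())
    return counts


# ---------------------------------------------------------------------------
# Ground-truth recovery


@dataclass
class RecoveryReport:
    """Hungarian-matched correlation between true and estimated expressions."""

    pairs: pd.DataFrame  # true_source, est_source, abs_r, sign
    mean_abs_r: float
    min_abs_r: float
    n_excluded: int

    def matched_estimates(self) -> dict[int, int]:
        return dict(zip(self.pairs["true_source"], self.pairs["est_source"]))


def recovery_score(S_true: np.ndarray, S_est: np.ndarray) -> RecoveryReport:
    """Optimal |correlation| assignment of estimated to true sources.

    Requires the same sample count and ``m_true <= m_est``; extra estimated
    sources stay unmatched. Constant rows have undefined correlation and are
    excluded with a warning. The score is invariant to permutation, sign
    flips and positive rescaling of either input's rows.
    """
    S_true = np.atleast_2d(np.asarray(S_true, dtype=float))
    S_est = np.atleast_2d(np.asarray(S_est, dtype=float))
    if S_true.shape[1] != S_est.shape[1]:
        raise ValueError("sample counts differ")
    if S_true.shape[0] > S_est.shape[0]:
        raise ValueError("need m_true <= m_est")
    ok_t = S_true.std(axis=1) > 0
    ok_e = S_est.std(axis=1) > 0
    n_excluded = int((~ok_t).sum() + (~ok_e).sum())
    if n_excluded:
        logger.warning("excluding %d constant rows from recovery matching", n_excluded)
    idx_t = np.flatnonzero(ok_t)
    idx_e = np.flatnonzero(ok_e)
    C = np.corrcoef(S_true[idx_t], S_est[idx_e])[: len(idx_t), len(idx_t):]
    rows, cols = linear_sum_assignment(-np.abs(C))
    pairs = pd.DataFrame(
        {
            "true_source": idx_t[rows],
            "est_source": idx_e[cols],
            "abs_r": np.abs(C[rows, cols]),
            "sign": np.sign(C[rows, cols]).astype(int),
        }
    ).sort_values("true_source").reset_index(drop=True)
    return RecoveryReport(
        pairs=pairs,
        mean_abs_r=float(pairs["abs_r"].mean()),
        min_abs_r=float(pairs["abs_r"].min()),
        n_excluded=n_excluded,
    )
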
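"""Per-mode transformations from point events to continuous-time curves.

Sparse, irregular point observations are converted into dense curves that are
defined (finite) at every day of a record's span, one transformation per data
mode:

* laboratory tests — shape-preserving piecewise-cubic (PCHIP) interpolation
  through the observations, constant extrapolation beyond the first/last
  observation, constant population median when a test was never observed;
* billing codes — Gaussian-kernel event-rate estimate (events/year) with
  reflection boundary correction, stored on the log scale so that signature
  weights back-transform multiplicatively;
* medications — piecewise-constant 0/1 presence over a fixed persistence
  window after each mention;
* demographics — constant 0/1 level indicators and a linearly increasing age
  curve.

Every constructor is a deterministic function of its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .ehr_data import (
    CodeEvent,
    Demographics,
    LabObservation,
    MedicationMention,
    PatientRecord,
    VariableCatalog,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

DEFAULT_BANDWIDTH_DAYS = 180.0
DEFAULT_FLOOR_RATE = 0.01  # events/year
DEFAULT_PERSISTENCE_DAYS = 90.0


class Curve:
    """A finite-valued function of record time (days)."""

    mode: str = ""
    transform: str = "identity"  # value scale: "identity" or "log"

    def evaluate(self, days) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, days) -> np.ndarray:
        return self.evaluate(days)


@dataclass
class ConstantCurve(Curve):
    value: float
    mode: str = ""
    transform: str = "identity"

    def evaluate(self, days) -> np.ndarray:
        return np.full_like(np.asarray(days, dtype=float), self.value)


@dataclass
class LabCurve(Curve):
    """PCHIP through observations with constant extrapolation."""

    days: np.ndarray
    values: np.ndarray
    mode: str = "lab"
    transform: str = "identity"

    def __post_init__(self) -> None:
        self._interp = PchipInterpolator(self.days, self.values, extrapolate=False)

    def evaluate(self, days) -> np.ndarray:
        t = np.clip(np.asarray(days, dtype=float), self.days[0], self.days[-1])
        return self._interp(t)


@dataclass
class CodeIntensityCurve(Curve):
    """log(rate + floor) where rate is a reflected-Gaussian-kernel estimate.

    The kernel density over event days is reflected at both record boundaries
    so that the rate integrates back to the event count, then scaled to
    events/year.
    """

    event_days: np.ndarray
    span_days: float
    bandwidth_days: float = DEFAULT_BANDWIDTH_DAYS
    floor_rate: float = DEFAULT_FLOOR_RATE
    mode: str = "code"
    transform: str = "log"

    def rate(self, days) -> np.ndarray:
        """Event rate in events/year at the given days."""
        t = np.atleast_1d(np.asarray(days, dtype=float))
        d = self.event_days[None, :]
        h = self.bandwidth_days
        dens = (
            norm.pdf(t[:, None], d, h)
            + norm.pdf(t[:, None], -d, h)
            + norm.pdf(t[:, None], 2.0 * self.span_days - d, h)
        ).sum(axis=1)
        return dens * DAYS_PER_YEAR

    def evaluate(self, days) -> np.ndarray:
        out = np.log(self.rate(days) + self.floor_rate)
        return out.reshape(np.shape(days)) if np.ndim(days) else out[0]


@dataclass
class StepCurve(Curve):
    """Right-open piecewise-constant curve from sorted breakpoints."""

    breakpoints: np.ndarray  # strictly increasing days
    levels: np.ndarray  # len(breakpoints) + 1 values, levels[0] before first bp
    mode: str = "med"
    transform: str = "identity"

    def evaluate(self, days) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints, np.asarray(days, dtype=float), side="right")
        return np.asarray(self.levels, dtype=float)[idx]


@dataclass
class AgeCurve(Curve):
    """Age in years as a linear function of record day."""

    birth_day_offset: float
    mode: str = "demo"
    transform: str = "identity"

    def evaluate(self, days) -> np.ndarray:
        return (np.asarray(days, dtype=float) - self.birth_day_offset) / DAYS_PER_YEAR


def lab_curve(observations: Sequence[LabObservation], population_median: float) -> Curve:
    """Dense curve through a test's observations.

    Same-day duplicates are averaged before fitting. With no observations the
    curve is the constant population median; with one it is constant at that
    value; with two or more it is the shape-preserving PCHIP interpolant,
    exact at every observation, clamped outside the observed range.
    """
    if not np.isfinite(population_median):
        raise ValueError("population_median must be finite")
    if not observations:
        return ConstantCurve(float(population_median), mode="lab")
    days = np.array([o.day for o in observations], dtype=float)
    vals = np.array([o.value for o in observations], dtype=float)
    order = np.argsort(days, kind="stable")
    days, vals = days[order], vals[order]
    uniq, inverse = np.unique(days, return_inverse=True)
    if len(uniq) < len(days):
        logger.debug("averaging %d same-day duplicate lab observations", len(days) - len(uniq))
        vals = np.bincount(inverse, weights=vals) / np.bincount(inverse)
        days = uniq
    if len(days) == 1:
        return ConstantCurve(float(vals[0]), mode="lab")
    return LabCurve(days, vals)


def code_intensity_curve(
    events: Sequence[CodeEvent],
    span_days: float,
    bandwidth_days: float = DEFAULT_BANDWIDTH_DAYS,
    floor_rate: float = DEFAULT_FLOOR_RATE,
) -> Curve:
    """Smoothed log event-rate curve for one billing code."""
    if span_days <= 0:
        raise ValueError("span_days must be > 0")
    if bandwidth_days <= 0 or floor_rate <= 0:
        raise ValueError("bandwidth_days and floor_rate must be > 0")
    if not events:
        return ConstantCurve(float(np.log(floor_rate)), mode="code", transform="log")
    days = np.sort(np.array([e.day for e in events], dtype=float))
    return CodeIntensityCurve(days, float(span_days), bandwidth_days, floor_rate)


def medication_curve(
    mentions: Sequence[MedicationMention],
    persistence_days: float = DEFAULT_PERSISTENCE_DAYS,
) -> Curve:
    """0/1 presence curve: 1 on the union of [day, day + persistence] windows."""
    if persistence_days <= 0:
        raise ValueError("persistence_days must be > 0")
    if not mentions:
        return ConstantCurve(0.0, mode="med")
    starts = np.sort(np.array([m.day for m in mentions], dtype=float))
    intervals: list[list[float]] = []
    for s in starts:
        e = s + persistence_days
        if intervals and s <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], e)
        else:
            intervals.append([s, e])
    bps, levels = [], [0.0]
    for s, e in intervals:
        bps += [s, e]
        levels += [1.0, 0.0]
    # presence is inclusive at both window ends: shift the closing breakpoint
    # by the smallest representable step so day == end still evaluates to 1
    bp = np.array(bps, dtype=float)
    bp[1::2] = np.nextafter(bp[1::2], np.inf)
    return StepCurve(bp, np.array(levels), mode="med")


def demographic_curves(demo: Demographics, catalog: VariableCatalog) -> dict[str, Curve]:
    """Constant indicator curves per declared demographic level, plus age."""
    out: dict[str, Curve] = {}
    for entry in catalog:
        if entry.mode != "demo":
            continue
        voc = entry.source_vocabulary_id
        if voc == "age":
            out[entry.variable_id] = AgeCurve(demo.birth_day_offset)
        elif "=" in voc:
            fld, level = voc.split("=", 1)
            actual = getattr(demo, fld, None)
            if actual is None:
                logger.warning("unknown demographic field %r; zero indicator", fld)
            out[entry.variable_id] = ConstantCurve(
                1.0 if actual == level else 0.0, mode="demo"
            )
        else:
            raise ValueError(f"unrecognized demographic variable {voc!r}")
    return out


@dataclass
class CurveSet:
    """All of one record's curves, complete over the variable catalog."""

    record_id: str
    span_days: float
    curves: dict[str, Curve]

    def evaluate_at(self, day: float, catalog: VariableCatalog) -> np.ndarray:
        """Cross-section vector in catalog row order."""
        return np.array(
            [float(np.asarray(self.curves[v].evaluate(day)).ravel()[0]) for v in catalog.variable_ids]
        )


@dataclass
class CurveParams:
    """Tunable per-mode transformation parameters."""

    bandwidth_days: float = DEFAULT_BANDWIDTH_DAYS
    floor_rate: float = DEFAULT_FLOOR_RATE
    persistence_days: float = DEFAULT_PERSISTENCE_DAYS


def population_medians(
    records: Sequence[PatientRecord], catalog: VariableCatalog
) -> dict[str, float]:
    """Per-test median over all observations in the cohort (0.0 if never seen)."""
    values: dict[str, list[float]] = {}
    for rec in records:
        for o in rec.labs:
            values.setdefault(f"lab:{o.test_id}", []).append(o.value)
    out = {}
    for entry in catalog:
        if entry.mode == "lab":
            vals = values.get(entry.variable_id)
            out[entry.variable_id] = float(np.median(vals)) if vals else 0.0
    return out


def curvesets_to_frame(curvesets: Sequence[CurveSet]):
    """Serialize curve definitions to a long-format table.

    Each curve's defining data (knots, event days, breakpoints or constants)
    is stored, so reconstruction is exact rather than a resampling.
    """
    import pandas as pd

    rows = []
    for cs in curvesets:
        for vid, c in cs.curves.items():
            base = dict(
                record_id=cs.record_id, variable_id=vid, span_days=cs.span_days,
                bandwidth_days=np.nan, floor_rate=np.nan,
            )
            if isinstance(c, LabCurve):
                for d, v in zip(c.days, c.values):
                    rows.append({**base, "kind": "pchip", "day": d, "value": v})
            elif isinstance(c, CodeIntensityCurve):
                for d in c.event_days:
                    rows.append({**base, "kind": "codekernel", "day": d, "value": np.nan,
                                 "bandwidth_days": c.bandwidth_days, "floor_rate": c.floor_rate})
            elif isinstance(c, StepCurve):
                for d, v in zip(c.breakpoints, c.levels[1:]):
                    rows.append({**base, "kind": "step", "day": d, "value": v})
            elif isinstance(c, AgeCurve):
                rows.append({**base, "kind": "age", "day": np.nan, "value": c.birth_day_offset})
            elif isinstance(c, ConstantCurve):
                rows.append({**base, "kind": f"const:{c.mode}:{c.transform}",
                             "day": np.nan, "value": c.value})
            else:  # pragma: no cover
                raise TypeError(f"unserializable curve type {type(c).__name__}")
    return pd.DataFrame(rows)


def curvesets_from_frame(df) -> list[CurveSet]:
    """Inverse of :func:`curvesets_to_frame`."""
    out = []
    for rid, grec in df.groupby("record_id", sort=False):
        curves: dict[str, Curve] = {}
        span = float(grec["span_days"].iloc[0])
        for vid, g in grec.groupby("variable_id", sort=False):
            kind = g["kind"].iloc[0]
            if kind == "pchip":
                g = g.sort_values("day")
                curves[vid] = LabCurve(g["day"].to_numpy(float), g["value"].to_numpy(float))
            elif kind == "codekernel":
                curves[vid] = CodeIntensityCurve(
                    np.sort(g["day"].to_numpy(float)), span,
                    float(g["bandwidth_days"].iloc[0]), float(g["floor_rate"].iloc[0]),
                )
            elif kind == "step":
                g = g.sort_values("day")
                curves[vid] = StepCurve(
                    g["day"].to_numpy(float),
                    np.concatenate([[0.0], g["value"].to_numpy(float)]),
                )
            elif kind == "age":
                curves[vid] = AgeCurve(float(g["value"].iloc[0]))
            elif kind.startswith("const:"):
                _, mode, transform = kind.split(":")
                curves[vid] = ConstantCurve(float(g["value"].iloc[0]), mode, transform)
            else:
                raise ValueError(f"unknown curve kind {kind!r}")
        out.append(CurveSet(str(rid), span, curves))
    return out


def build_curveset(
    record: PatientRecord,
    catalog: VariableCatalog,
    medians: Mapping[str, float],
    params: CurveParams | None = None,
) -> CurveSet:
    """Construct every catalog variable's curve for one record."""
    params = params or CurveParams()
    labs_by_test: dict[str, list[LabObservation]] = {}
    for o in record.labs:
        labs_by_test.setdefault(o.test_id, []).append(o)
    codes_by_id: dict[str, list[CodeEvent]] = {}
    for e in record.codes:
        codes_by_id.setdefault(e.code_id, []).append(e)
    meds_by_id: dict[str, list[MedicationMention]] = {}
    for m in record.meds:
        meds_by_id.setdefault(m.med_id, []).append(m)

    curves: dict[str, Curve] = demographic_curves(record.demographics, catalog)
    for entry in catalog:
        vid, voc = entry.variable_id, entry.source_vocabulary_id
        if entry.mode == "lab":
            curves[vid] = lab_curve(labs_by_test.get(voc, []), medians.get(vid, 0.0))
        elif entry.mode == "code":
            curves[vid] = code_intensity_curve(
                codes_by_id.get(voc, []),
                max(record.span_days, 1.0),
                params.bandwidth_days,
                params.floor_rate,
            )
        elif entry.mode == "med":
            curves[vid] = medication_curve(meds_by_id.get(voc, []), params.persistence_days)
    return CurveSet(record.record_id, record.span_days, curves)
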
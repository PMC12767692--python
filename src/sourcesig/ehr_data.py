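"""Canonical in-memory model for multi-modal EHR records.

A :class:`PatientRecord` holds one subject's event streams — laboratory
observations, billing-code events, and medication mentions — together with
demographics, an optional index-event day (the day the indeterminate pulmonary
nodule was first coded) and an optional malignant/benign outcome label.

Time is measured in fractional days from each record's first event (day 0);
all downstream computation is relative, so no absolute calendar convention is
needed.

The canonical on-disk format is one comma-delimited table per mode, keyed by
``record_id``:

* ``labs.csv``:  record_id, day, test_id, value
* ``codes.csv``: record_id, day, code_id
* ``meds.csv``:  record_id, day, med_id
* ``demo.csv``:  record_id, sex, race, birth_day_offset, span_days
* ``index.csv``: record_id, index_day, label   (optional rows per record)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_LEVELS = ("male", "female")
RACE_LEVELS = ("white", "black", "other")
UNKNOWN = "unknown"

Mode = Literal["lab", "code", "med", "demo"]
Label = Literal["positive", "negative"]


class SchemaError(ValueError):
    """Raised when an input table is missing a required column."""


@dataclass(frozen=True)
class LabObservation:
    test_id: str
    day: float
    value: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"lab day must be >= 0, got {self.day}")
        if not np.isfinite(self.value):
            raise ValueError(f"lab value must be finite, got {self.value}")


@dataclass(frozen=True)
class CodeEvent:
    code_id: str
    day: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"code day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class MedicationMention:
    med_id: str
    day: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"medication day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class Demographics:
    """Categorical demographics plus a birth-day offset.

    ``birth_day_offset`` is the (typically negative) day of birth on the
    record's own clock, so age in years at day ``d`` is
    ``(d - birth_day_offset) / 365.25``.
    """

    sex: str = UNKNOWN
    race: str = UNKNOWN
    birth_day_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS + (UNKNOWN,):
            raise ValueError(f"unknown sex level {self.sex!r}")
        if self.race not in RACE_LEVELS + (UNKNOWN,):
            raise ValueError(f"unknown race level {self.race!r}")


@dataclass
class PatientRecord:
    """One subject's multi-modal event streams on a relative-day clock."""

    record_id: str
    span_days: float
    labs: list[LabObservation] = field(default_factory=list)
    codes: list[CodeEvent] = field(default_factory=list)
    meds: list[MedicationMention] = field(default_factory=list)
    demographics: Demographics = field(default_factory=Demographics)
    index_day: float | None = None
    label: Label | None = None

    def __post_init__(self) -> None:
        for ev in (*self.labs, *self.codes, *self.meds):
            if ev.day > self.span_days:
                raise ValueError(
                    f"event day {ev.day} exceeds span_days {self.span_days} "
                    f"in record {self.record_id}"
                )
        if self.index_day is not None and self.index_day > self.span_days:
            raise ValueError("index_day exceeds span_days")

    def sorted(self) -> "PatientRecord":
        return replace(
            self,
            labs=sorted(self.labs, key=lambda o: (o.day, o.test_id)),
            codes=sorted(self.codes, key=lambda o: (o.day, o.code_id)),
            meds=sorted(self.meds, key=lambda o: (o.day, o.med_id)),
        )


@dataclass(frozen=True)
class VariableDef:
    variable_id: str
    mode: Mode
    source_vocabulary_id: str


class VariableCatalog:
    """Ordered list of variable descriptors; the order defines matrix rows."""

    def __init__(self, entries: Sequence[VariableDef]):
        ids = [e.variable_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("variable_ids must be unique")
        self._entries = tuple(entries)
        self._index = {v: i for i, v in enumerate(ids)}

    @property
    def entries(self) -> tuple[VariableDef, ...]:
        return self._entries

    @property
    def variable_ids(self) -> list[str]:
        return [e.variable_id for e in self._entries]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def index_of(self, variable_id: str) -> int:
        return self._index[variable_id]

    def mode_of(self, variable_id: str) -> Mode:
        return self._entries[self._index[variable_id]].mode

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable_id": [e.variable_id for e in self._entries],
                "mode": [e.mode for e in self._entries],
                "source_vocabulary_id": [e.source_vocabulary_id for e in self._entries],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VariableCatalog":
        return cls(
            [
                VariableDef(str(r.variable_id), r.mode, str(r.source_vocabulary_id))
                for r in df.itertuples()
            ]
        )

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord]) -> "VariableCatalog":
        """Build a catalog from the union of vocabularies observed in a cohort.

        Demographic indicator variables (one per declared sex/race level,
        plus age) are always included so every record yields a complete curve
        set.
        """
        labs: set[str] = set()
        codes: set[str] = set()
        meds: set[str] = set()
        for rec in records:
            labs.update(o.test_id for o in rec.labs)
            codes.update(e.code_id for e in rec.codes)
            meds.update(m.med_id for m in rec.meds)
        entries = [VariableDef(f"lab:{t}", "lab", t) for t in sorted(labs)]
        entries += [VariableDef(f"code:{c}", "code", c) for c in sorted(codes)]
        entries += [VariableDef(f"med:{m}", "med", m) for m in sorted(meds)]
        entries += [VariableDef(f"demo:sex={s}", "demo", f"sex={s}") for s in SEX_LEVELS]
        entries += [VariableDef(f"demo:race={r}", "demo", f"race={r}") for r in RACE_LEVELS]
        entries += [VariableDef("demo:age", "demo", "age")]
        return cls(entries)


# ---------------------------------------------------------------------------
# Readers / writers


_REQUIRED = {
    "labs": ["record_id", "day", "test_id", "value"],
    "codes": ["record_id", "day", "code_id"],
    "meds": ["record_id", "day", "med_id"],
    "demo": ["record_id", "sex", "race", "birth_day_offset", "span_days"],
    "index": ["record_id", "index_day"],
}


def _load(path: Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns {missing}")
    if "day" in df.columns and (df["day"] < 0).any():
        raise ValueError(f"{path} contains negative event days")
    return df


def read_records(store: str | Path) -> list[PatientRecord]:
    """Read a cohort from a directory of canonical delimited tables.

    ``demo.csv`` defines the record set; event tables and ``index.csv`` are
    optional. Events are returned sorted by day; counts are preserved
    row-for-row.
    """
    store = Path(store)
    demo = _load(store / "demo.csv", "demo")
    tables = {}
    for kind in ("labs", "codes", "meds"):
        p = store / f"{kind}.csv"
        tables[kind] = _load(p, kind) if p.exists() else None
    idx_path = store / "index.csv"
    idx = _load(idx_path, "index").set_index("record_id") if idx_path.exists() else None

    def events(kind: str, rid: str):
        df = tables[kind]
        if df is None:
            return iter(())
        return df[df["record_id"].astype(str) == rid].itertuples()

    records = []
    for row in demo.itertuples():
        rid = str(row.record_id)
        labs = [
            LabObservation(str(r.test_id), float(r.day), float(r.value))
            for r in events("labs", rid)
        ]
        codes = [CodeEvent(str(r.code_id), float(r.day)) for r in events("codes", rid)]
        meds = [MedicationMention(str(r.med_id), float(r.day)) for r in events("meds", rid)]
        index_day = None
        label = None
        if idx is not None and rid in idx.index:
            ival = idx.loc[rid, "index_day"]
            index_day = float(ival) if pd.notna(ival) else None
            if "label" in idx.columns and pd.notna(idx.loc[rid, "label"]):
                label = str(idx.loc[rid, "label"])
        records.append(
            PatientRecord(
                record_id=rid,
                span_days=float(row.span_days),
                labs=labs,
                codes=codes,
                meds=meds,
                demographics=Demographics(str(row.sex), str(row.race), float(row.birth_day_offset)),
                index_day=index_day,
                label=label,
            ).sorted()
        )
    return records


def write_records(records: Sequence[PatientRecord], store: str | Path) -> None:
    """Write a cohort as the canonical delimited tables (inverse of read)."""
    store = Path(store)
    store.mkdir(parents=True, exist_ok=True)
    labs, codes, meds, demo, index = [], [], [], [], []
    for rec in records:
        rec = rec.sorted()
        for o in rec.labs:
            labs.append((rec.record_id, o.day, o.test_id, o.value))
        for e in rec.codes:
            codes.append((rec.record_id, e.day, e.code_id))
        for m in rec.meds:
            meds.append((rec.record_id, m.day, m.med_id))
        d = rec.demographics
        demo.append((rec.record_id, d.sex, d.race, d.birth_day_offset, rec.span_days))
        if rec.index_day is not None or rec.label is not None:
            index.append((rec.record_id, rec.index_day, rec.label))
    pd.DataFrame(labs, columns=_REQUIRED["labs"]).to_csv(store / "labs.csv", index=False)
    pd.DataFrame(codes, columns=_REQUIRED["codes"]).to_csv(store / "codes.csv", index=False)
    pd.DataFrame(meds, columns=_REQUIRED["meds"]).to_csv(store / "meds.csv", index=False)
    pd.DataFrame(demo, columns=_REQUIRED["demo"]).to_csv(store / "demo.csv", index=False)
    pd.DataFrame(index, columns=["record_id", "index_day", "label"]).to_csv(
        store / "index.csv", index=False
    )


# ---------------------------------------------------------------------------
# Cohort operations


def truncate_at_index(record: PatientRecord) -> PatientRecord:
    """Drop everything after the index event; the record ends at index_day.

    Only events with ``day <= index_day`` survive and ``span_days`` becomes
    the index day, so no post-index information (except the label, which is
    untouched) remains. Idempotent.
    """
    if record.index_day is None:
        raise ValueError(f"record {record.record_id} has no index_day")
    t = record.index_day
    return replace(
        record,
        span_days=t,
        labs=[o for o in record.labs if o.day <= t],
        codes=[e for e in record.codes if e.day <= t],
        meds=[m for m in record.meds if m.day <= t],
    )


def assign_label(
    record: PatientRecord,
    malignancy_codes: set[str],
    window: tuple[float, float] = (4.0, 1095.0),
) -> Literal["positive", "negative", "excluded"]:
    """Outcome-labeling rule relative to the index event.

    ``positive`` iff any malignancy code falls in the closed window
    ``[lo, hi]`` days after the index day; ``excluded`` iff any malignancy
    code occurs before the window opens (same-day diagnoses and prior cancer
    history, which disqualify a record from the no-prior-cancer cohort);
    ``negative`` otherwise. The default window is days 4–1095 after nodule
    detection.
    """
    if not malignancy_codes:
        raise ValueError("malignancy_codes must be nonempty")
    if record.index_day is None:
        raise ValueError(f"record {record.record_id} has no index_day")
    lo, hi = window
    if lo > hi:
        raise ValueError("window lo must be <= hi")
    rel = [e.day - record.index_day for e in record.codes if e.code_id in malignancy_codes]
    if any(d < lo for d in rel):
        return "excluded"
    if any(lo <= d <= hi for d in rel):
        return "positive"
    return "negative"


def cohort_summary(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tidy per-stratum cohort summary.

    Rows are (stratum, statistic, value, pct, q25, q75): categorical strata
    report counts and percentages, per-record quantities report the median
    with the interquartile interval. Strata are the record labels (records
    without a label fall into ``"all"``).
    """
    if not records:
        raise ValueError("empty cohort")
    rows = []
    by_stratum: dict[str, list[PatientRecord]] = {}
    for rec in records:
        by_stratum.setdefault(rec.label or "all", []).append(rec)
    for stratum, recs in sorted(by_stratum.items()):
        n = len(recs)
        rows.append((stratum, "n_records", n, np.nan, np.nan, np.nan))
        for sex in SEX_LEVELS + (UNKNOWN,):
            c = sum(r.demographics.sex == sex for r in recs)
            if c:
                rows.append((stratum, f"sex={sex}", c, 100.0 * c / n, np.nan, np.nan))
        for race in RACE_LEVELS + (UNKNOWN,):
            c = sum(r.demographics.race == race for r in recs)
            if c:
                rows.append((stratum, f"race={race}", c, 100.0 * c / n, np.nan, np.nan))
        per_record = {
            "record_length_days": [r.span_days for r in recs],
            "n_codes": [len(r.codes) for r in recs],
            "n_labs": [len(r.labs) for r in recs],
            "n_meds": [len(r.meds) for r in recs],
            "unique_codes": [len({e.code_id for e in r.codes}) for r in recs],
            "unique_labs": [len({o.test_id for o in r.labs}) for r in recs],
            "unique_meds": [len({m.med_id for m in r.meds}) for r in recs],
        }
        for stat, vals in per_record.items():
            v = np.asarray(vals, dtype=float)
            rows.append(
                (
                    stratum,
                    stat,
                    float(np.median(v)),
                    np.nan,
                    float(np.percentile(v, 25)),
                    float(np.percentile(v, 75)),
                )
            )
    return pd.DataFrame(rows, columns=["stratum", "statistic", "value", "pct", "q25", "q75"])
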
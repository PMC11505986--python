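"""Cohort data model and table I/O for longitudinal claims-like survival data.

Two tables describe a cohort:

* a **patients** table, one row per subject, holding the time-fixed
  covariates recorded at diagnosis plus the right-censored outcome
  (follow-up ``duration`` in days and the death indicator ``event``);
* a **visits** table, one row per follow-up contact, holding the day of the
  visit, the patient's current age and comorbidity index, and the sets of
  treatment (codes 1..46) and adverse-event (codes 1..18) categories
  recorded at that visit.

Tables are comma-delimited text with a header; in-cell code lists use ";"
as separator (``treatments = "7;12"``).  Six prognostic scenarios partition
patients by stage (I/II/III) and hormone-receptor group (ER/PR+ vs ER/PR−):
a patient is ER/PR+ if either receptor is positive and ER/PR− only if both
are negative; patients with both receptors unknown belong to no scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "N_TREATMENT_CATEGORIES",
    "N_ADVERSE_EVENT_CATEGORIES",
    "PATIENT_COLUMNS",
    "VISIT_COLUMNS",
    "SCENARIOS",
    "PatientRecord",
    "VisitRecord",
    "Cohort",
    "ScenarioFilter",
    "TableDialect",
    "SchemaError",
    "RowValidationError",
    "read_patients",
    "read_visits",
    "write_patients",
    "write_visits",
    "select_scenario",
]

N_TREATMENT_CATEGORIES = 46
N_ADVERSE_EVENT_CATEGORIES = 18

PATIENT_COLUMNS = [
    "patient_id", "age_dx", "race", "marital", "stage", "grade", "laterality",
    "er", "pr", "her2", "comorbidity_dx", "duration", "event",
]
VISIT_COLUMNS = [
    "patient_id", "t", "age", "comorbidity_index", "treatments", "adverse_events",
]

_STAGES = ("I", "II", "III")
_RECEPTOR_LEVELS = ("+", "-", "unknown")


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class RowValidationError(ValueError):
    """A row violates a type or range constraint; carries the row index."""

    def __init__(self, row: int, fld: str, message: str):
        self.row = row
        self.field = fld
        super().__init__(f"row {row}, field '{fld}': {message}")


@dataclass(frozen=True)
class TableDialect:
    sep: str = ","
    list_sep: str = ";"


@dataclass
class PatientRecord:
    """Time-fixed covariates at diagnosis plus the (duration, event) outcome."""

    patient_id: str
    age_dx: float
    race: str
    marital: str
    stage: str
    grade: str
    laterality: str
    er: str
    pr: str
    her2: str
    comorbidity_dx: float
    duration: float
    event: int

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}, got {self.stage!r}")


@dataclass
class VisitRecord:
    """One follow-up contact: day, current age/comorbidity, code sets."""

    patient_id: str
    t: float
    age: float
    comorbidity_index: float
    treatments: frozenset[int] = field(default_factory=frozenset)
    adverse_events: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.t < 0:
            raise ValueError(f"visit time must be >= 0, got {self.t}")
        bad_tr = [c for c in self.treatments if not 1 <= c <= N_TREATMENT_CATEGORIES]
        if bad_tr:
            raise ValueError(f"treatment codes outside 1..{N_TREATMENT_CATEGORIES}: {bad_tr}")
        bad_ae = [c for c in self.adverse_events if not 1 <= c <= N_ADVERSE_EVENT_CATEGORIES]
        if bad_ae:
            raise ValueError(f"adverse-event codes outside 1..{N_ADVERSE_EVENT_CATEGORIES}: {bad_ae}")


@dataclass(frozen=True)
class ScenarioFilter:
    """One of the six prognostic scenarios: a stage and a receptor group."""

    stage: str
    erpr: str  # "positive" | "negative"

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}")
        if self.erpr not in ("positive", "negative"):
            raise ValueError("erpr must be 'positive' or 'negative'")

    @property
    def label(self) -> str:
        sign = "+" if self.erpr == "positive" else "-"
        return f"stage {self.stage}, ER/PR{sign}"


#: The six scenarios in their conventional order (1..6).
SCENARIOS: tuple[ScenarioFilter, ...] = tuple(
    ScenarioFilter(stage, erpr)
    for erpr in ("positive", "negative")
    for stage in _STAGES
)


class Cohort:
    """Patients and their visits, held as validated pandas DataFrames."""

    def __init__(self, patients: pd.DataFrame, visits: pd.DataFrame):
        self.patients = patients.reset_index(drop=True)
        self.visits = visits.reset_index(drop=True)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return self.patients["patient_id"].tolist()

    def validate(self) -> None:
        for col in PATIENT_COLUMNS:
            if col not in self.patients.columns:
                raise SchemaError(f"patients table missing column '{col}'")
        for col in VISIT_COLUMNS:
            if col not in self.visits.columns:
                raise SchemaError(f"visits table missing column '{col}'")
        if self.patients["patient_id"].duplicated().any():
            dupes = self.patients.loc[self.patients["patient_id"].duplicated(), "patient_id"]
            raise ValueError(f"duplicate patient_id values: {sorted(set(dupes))[:5]}")
        if (self.patients["duration"] <= 0).any():
            raise ValueError("durations must be > 0")
        if not self.patients["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        known = set(self.patients["patient_id"])
        orphans = set(self.visits["patient_id"]) - known
        if orphans:
            raise ValueError(f"visits reference unknown patients: {sorted(orphans)[:5]}")

    # -- record-level views ----------------------------------------------

    def patient_records(self) -> list[PatientRecord]:
        return [PatientRecord(**row) for row in self.patients[PATIENT_COLUMNS].to_dict("records")]

    def visits_of(self, patient_id: str) -> list[VisitRecord]:
        sub = self.visits[self.visits["patient_id"] == patient_id].sort_values("t")
        return [
            VisitRecord(
                patient_id=r.patient_id,
                t=float(r.t),
                age=float(r.age),
                comorbidity_index=float(r.comorbidity_index),
                treatments=_parse_codes(r.treatments),
                adverse_events=_parse_codes(r.adverse_events),
            )
            for r in sub.itertuples()
        ]

    def to_csv(self, patients_path, visits_path) -> None:
        """Write both tables in the documented dialect (deterministic bytes)."""
        self.patients[PATIENT_COLUMNS].to_csv(patients_path, index=False)
        self.visits[VISIT_COLUMNS].to_csv(visits_path, index=False)

    @classmethod
    def from_csv(cls, patients_path, visits_path,
                 dialect: TableDialect = TableDialect()) -> "Cohort":
        p = read_patients(patients_path, dialect)
        v = read_visits(visits_path, dialect)
        return cls.from_records(p, v)

    @classmethod
    def from_records(cls, patients: list[PatientRecord],
                     visits: list[VisitRecord]) -> "Cohort":
        pdf = pd.DataFrame([vars(p) for p in patients], columns=PATIENT_COLUMNS)
        vdf = pd.DataFrame(
            [
                {
                    "patient_id": v.patient_id,
                    "t": v.t,
                    "age": v.age,
                    "comorbidity_index": v.comorbidity_index,
                    "treatments": _format_codes(v.treatments),
                    "adverse_events": _format_codes(v.adverse_events),
                }
                for v in visits
            ],
            columns=VISIT_COLUMNS,
        )
        return cls(pdf, vdf)


def _parse_codes(cell, list_sep: str = ";") -> frozenset[int]:
    if isinstance(cell, frozenset):
        return cell
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(list_sep) if tok.strip())


def _format_codes(codes: frozenset[int], list_sep: str = ";") -> str:
    return list_sep.join(str(c) for c in sorted(codes))


# ---------------------------------------------------------------------------
# readers / writers


def read_patients(path, dialect: TableDialect = TableDialect()) -> list[PatientRecord]:
    """Read a patients table, rejecting (not coercing) malformed rows."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patients table missing required columns: {missing}")
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            rec = PatientRecord(
                patient_id=d["patient_id"],
                age_dx=_num(d["age_dx"], i, "age_dx"),
                race=d["race"],
                marital=d["marital"],
                stage=d["stage"],
                grade=d["grade"],
                laterality=d["laterality"],
                er=d["er"],
                pr=d["pr"],
                her2=d["her2"],
                comorbidity_dx=_num(d["comorbidity_dx"], i, "comorbidity_dx"),
                duration=_num(d["duration"], i, "duration"),
                event=int(_num(d["event"], i, "event")),
            )
        except ValueError as exc:
            if isinstance(exc, RowValidationError):
                raise
            raise RowValidationError(i, "record", str(exc)) from exc
        records.append(rec)
    return records


def read_visits(path, dialect: TableDialect = TableDialect()) -> list[VisitRecord]:
    """Read a visits table; code lists become sets, output sorted by (id, t)."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"visits table missing required columns: {missing}")
    records: list[VisitRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            rec = VisitRecord(
                patient_id=d["patient_id"],
                t=_num(d["t"], i, "t"),
                age=_num(d["age"], i, "age"),
                comorbidity_index=_num(d["comorbidity_index"], i, "comorbidity_index"),
                treatments=_parse_codes(d["treatments"], dialect.list_sep),
                adverse_events=_parse_codes(d["adverse_events"], dialect.list_sep),
            )
        except ValueError as exc:
            if isinstance(exc, RowValidationError):
                raise
            raise RowValidationError(i, "record", str(exc)) from exc
        records.append(rec)
    records.sort(key=lambda v: (v.patient_id, v.t))
    return records


def _num(text: str, row: int, fld: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise RowValidationError(row, fld, f"cannot parse {text!r} as a number") from None


def write_patients(records: list[PatientRecord], path,
                   dialect: TableDialect = TableDialect()) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=PATIENT_COLUMNS)
    df.to_csv(path, sep=dialect.sep, index=False)


def write_visits(records: list[VisitRecord], path,
                 dialect: TableDialect = TableDialect()) -> None:
    rows = [
        {
            "patient_id": v.patient_id,
            "t": v.t,
            "age": v.age,
            "comorbidity_index": v.comorbidity_index,
            "treatments": _format_codes(v.treatments, dialect.list_sep),
            "adverse_events": _format_codes(v.adverse_events, dialect.list_sep),
        }
        for v in records
    ]
    pd.DataFrame(rows, columns=VISIT_COLUMNS).to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# scenario selection


def erpr_group(er: pd.Series, pr: pd.Series) -> pd.Series:
    """Hormone-receptor group: 'positive' if either receptor is +, 'negative'
    if both are −, 'unknown' otherwise."""
    out = pd.Series("unknown", index=er.index)
    out[(er == "+") | (pr == "+")] = "positive"
    out[(er == "-") & (pr == "-")] = "negative"
    return out


def select_scenario(cohort: Cohort, scenario: ScenarioFilter) -> Cohort:
    """Return the sub-cohort matching one prognostic scenario.

    The input cohort is not modified; visits of excluded patients are
    dropped.  An empty result triggers a warning, not an error.
    """
    p = cohort.patients
    keep = (p["stage"] == scenario.stage) & (erpr_group(p["er"], p["pr"]) == scenario.erpr)
    sub_p = p[keep].copy()
    if sub_p.empty:
        warnings.warn(f"scenario {scenario.label} selected no patients", stacklevel=2)
    kept_ids = set(sub_p["patient_id"])
    sub_v = cohort.visits[cohort.visits["patient_id"].isin(kept_ids)].copy()
    return Cohort(sub_p, sub_v)
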
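"""Event and visit data structures for outpatient prescription streams.

Raw inputs are two delimited event tables -- drug prescriptions and
diagnoses -- plus attribute lookup tables for patients, physicians and
institutions.  Rows sharing the composite key (institution, patient,
calendar date) belong to the same outpatient visit: a patient receiving
three drugs and two diagnoses at one clinic on one day is a single visit.

The module validates and parses the event files, assembles visits, and
applies the institution inclusion rule (institutions contributing fewer
than a minimum number of calendar months of data are dropped).
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

log = logging.getLogger(__name__)

#: Default study window (inclusive).
DEFAULT_WINDOW = (dt.date(2017, 6, 1), dt.date(2021, 7, 31))

MISSING = "missing"

PRESCRIPTION_COLUMNS = [
    "institution_id", "patient_id", "visit_date",
    "drug_code", "drug_name", "route", "physician_id",
]
DIAGNOSIS_COLUMNS = [
    "institution_id", "patient_id", "visit_date",
    "code_system", "diagnosis_code",
]

ROUTES = {"oral", "parenteral", "other", "unknown"}
CODE_SYSTEMS = {"ICD10", "TCM"}


@dataclass(frozen=True)
class PrescriptionEvent:
    institution_id: str
    patient_id: str
    visit_date: dt.date
    drug_code: str
    drug_name: str
    route: str = "unknown"
    physician_id: str = MISSING

    @property
    def key(self) -> tuple[str, str, dt.date]:
        return (self.institution_id, self.patient_id, self.visit_date)


@dataclass(frozen=True)
class DiagnosisEvent:
    institution_id: str
    patient_id: str
    visit_date: dt.date
    code_system: str
    diagnosis_code: str

    @property
    def key(self) -> tuple[str, str, dt.date]:
        return (self.institution_id, self.patient_id, self.visit_date)


@dataclass(frozen=True)
class PatientAttrs:
    age_group: str = MISSING    # <6, 6-17, 18-44, 45-64, >=65
    gender: str = MISSING       # male, female
    payment: str = MISSING      # insurance, out_of_pocket


@dataclass(frozen=True)
class PhysicianAttrs:
    age_group: str = MISSING    # <30, 30-39, 40-49, 50-59, >=60
    gender: str = MISSING
    education: str = MISSING    # bachelor_or_above, high_school_or_below


@dataclass(frozen=True)
class InstitutionAttrs:
    area_type: str = MISSING    # urban, rural
    level: str = MISSING        # CHSC_TH, CHSS_VC
    months_with_data: int = 0


@dataclass
class Visit:
    """One patient-day-institution unit.

    ``antibiotics`` is populated by :func:`abxaudit.catalog.annotate_visits`
    with ``(PrescriptionEvent, AntibioticEntry)`` pairs and is always a
    subset of ``prescriptions``.
    """

    institution_id: str
    patient_id: str
    visit_date: dt.date
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)
    prescriptions: list[PrescriptionEvent] = field(default_factory=list)
    antibiotics: list = field(default_factory=list)
    patient: PatientAttrs = field(default_factory=PatientAttrs)
    physician_id: str = MISSING
    physician: PhysicianAttrs = field(default_factory=PhysicianAttrs)
    institution: InstitutionAttrs = field(default_factory=InstitutionAttrs)

    @property
    def key(self) -> tuple[str, str, dt.date]:
        return (self.institution_id, self.patient_id, self.visit_date)

    @property
    def has_antibiotic(self) -> bool:
        return len(self.antibiotics) > 0


@dataclass
class ReadReport:
    """Row-level accounting for one event file."""

    n_rows: int = 0
    n_accepted: int = 0
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_accepted


def _parse_date(value: str) -> dt.date | None:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except (ValueError, TypeError):
        return None


def read_events(path, schema: str, window=DEFAULT_WINDOW):
    """Read one event file and return ``(events, ReadReport)``.

    ``schema`` is ``"prescription"`` or ``"diagnosis"``.  Rows with an
    unparseable date, an empty code, an unknown code system, or a date
    outside the study ``window`` are rejected and counted by reason; a
    missing required column is a hard failure naming the column.
    """
    if schema == "prescription":
        required = PRESCRIPTION_COLUMNS
    elif schema == "diagnosis":
        required = DIAGNOSIS_COLUMNS
    else:
        raise ValueError(f"unknown schema {schema!r}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    lo, hi = window
    events: list = []
    report = ReadReport(n_rows=len(df))
    for row in df.itertuples(index=False):
        date = _parse_date(row.visit_date)
        if date is None:
            report.reasons["bad_date"] += 1
            continue
        if not (lo <= date <= hi):
            report.reasons["outside_window"] += 1
            continue
        if schema == "prescription":
            if not str(row.drug_code).strip():
                report.reasons["empty_code"] += 1
                continue
            route = str(row.route).strip() or "unknown"
            if route not in ROUTES:
                route = "unknown"
            events.append(PrescriptionEvent(
                institution_id=str(row.institution_id),
                patient_id=str(row.patient_id),
                visit_date=date,
                drug_code=str(row.drug_code).strip(),
                drug_name=str(row.drug_name).strip(),
                route=route,
                physician_id=str(row.physician_id).strip() or MISSING,
            ))
        else:
            if not str(row.diagnosis_code).strip():
                report.reasons["empty_code"] += 1
                continue
            system = str(row.code_system).strip()
            if system not in CODE_SYSTEMS:
                report.reasons["unknown_code_system"] += 1
                continue
            events.append(DiagnosisEvent(
                institution_id=str(row.institution_id),
                patient_id=str(row.patient_id),
                visit_date=date,
                code_system=system,
                diagnosis_code=str(row.diagnosis_code).strip(),
            ))
    report.n_accepted = len(events)
    if report.n_rejected:
        log.info("%s: rejected %d of %d rows (%s)", path,
                 report.n_rejected, report.n_rows, dict(report.reasons))
    return events, report


def read_attribute_tables(patients_path=None, physicians_path=None,
                          institutions_path=None):
    """Read attribute CSVs into id -> attrs dictionaries."""
    patients: dict[str, PatientAttrs] = {}
    physicians: dict[str, PhysicianAttrs] = {}
    institutions: dict[str, InstitutionAttrs] = {}
    if patients_path is not None:
        df = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
        for r in df.itertuples(index=False):
            patients[r.patient_id] = PatientAttrs(r.age_group, r.gender, r.payment)
    if physicians_path is not None:
        df = pd.read_csv(physicians_path, dtype=str, keep_default_na=False)
        for r in df.itertuples(index=False):
            physicians[r.physician_id] = PhysicianAttrs(
                r.age_group, r.gender, r.education)
    if institutions_path is not None:
        df = pd.read_csv(institutions_path, dtype=str, keep_default_na=False)
        for r in df.itertuples(index=False):
            institutions[r.institution_id] = InstitutionAttrs(r.area_type, r.level)
    return patients, physicians, institutions


def _majority_physician(prescriptions: list[PrescriptionEvent]) -> str:
    """Most frequent physician on the visit; ties broken by file order."""
    counts: dict[str, int] = {}
    for ev in prescriptions:
        counts[ev.physician_id] = counts.get(ev.physician_id, 0) + 1
    if not counts:
        return MISSING
    best = max(counts.values())
    for ev in prescriptions:        # first-in-file wins the tie
        if counts[ev.physician_id] == best:
            return ev.physician_id
    return MISSING


def assemble_visits(prescriptions, diagnoses, patients=None, physicians=None,
                    institutions=None) -> list[Visit]:
    """Group events by (institution, patient, date) into visits.

    Attribute lookup misses leave the visit in place with explicit
    ``missing`` attribute tokens (counted in the log).  Visits are
    returned sorted by key so downstream output is deterministic.
    """
    patients = patients or {}
    physicians = physicians or {}
    institutions = institutions or {}
    visits: dict[tuple, Visit] = {}

    def get(key) -> Visit:
        v = visits.get(key)
        if v is None:
            v = Visit(institution_id=key[0], patient_id=key[1], visit_date=key[2])
            visits[key] = v
        return v

    for ev in prescriptions:
        get(ev.key).prescriptions.append(ev)
    for ev in diagnoses:
        get(ev.key).diagnoses.append(ev)

    misses = Counter()
    for v in visits.values():
        v.physician_id = _majority_physician(v.prescriptions)
        if v.patient_id in patients:
            v.patient = patients[v.patient_id]
        else:
            misses["patient"] += 1
        if v.physician_id in physicians:
            v.physician = physicians[v.physician_id]
        else:
            misses["physician"] += 1
        if v.institution_id in institutions:
            v.institution = institutions[v.institution_id]
        else:
            misses["institution"] += 1
    if misses:
        log.info("attribute lookup misses: %s", dict(misses))
    return [visits[k] for k in sorted(visits)]


def filter_institutions(visits: list[Visit], min_months: int = 10):
    """Keep institutions with at least ``min_months`` distinct data months.

    Returns ``(kept_visits, exclusion_report)`` where the report is a
    DataFrame listing every institution with its month and visit counts
    and whether it was excluded.  ``months_with_data`` is recorded on the
    institution attributes of kept visits.
    """
    if min_months < 1:
        raise ValueError("min_months must be >= 1")
    months: dict[str, set] = {}
    counts: Counter = Counter()
    for v in visits:
        months.setdefault(v.institution_id, set()).add(
            (v.visit_date.year, v.visit_date.month))
        counts[v.institution_id] += 1
    rows = [
        {"institution_id": inst, "n_months": len(m),
         "n_visits": counts[inst], "excluded": len(m) < min_months}
        for inst, m in sorted(months.items())
    ]
    report = pd.DataFrame(rows, columns=["institution_id", "n_months",
                                         "n_visits", "excluded"])
    kept = []
    for v in visits:
        n_m = len(months[v.institution_id])
        if n_m >= min_months:
            v.institution = replace(v.institution, months_with_data=n_m)
            kept.append(v)
    n_excl = int(report["excluded"].sum())
    if n_excl:
        log.info("excluded %d institutions with < %d months of data",
                 n_excl, min_months)
    return kept, report


def visits_to_frames(visits: list[Visit]):
    """Write assembled visits back to event-table form (round-trip aid)."""
    rx_rows, dx_rows = [], []
    for v in visits:
        for ev in v.prescriptions:
            rx_rows.append({
                "institution_id": ev.institution_id,
                "patient_id": ev.patient_id,
                "visit_date": ev.visit_date.isoformat(),
                "drug_code": ev.drug_code, "drug_name": ev.drug_name,
                "route": ev.route, "physician_id": ev.physician_id,
            })
        for ev in v.diagnoses:
            dx_rows.append({
                "institution_id": ev.institution_id,
                "patient_id": ev.patient_id,
                "visit_date": ev.visit_date.isoformat(),
                "code_system": ev.code_system,
                "diagnosis_code": ev.diagnosis_code,
            })
    return (pd.DataFrame(rx_rows, columns=PRESCRIPTION_COLUMNS),
            pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLUMNS))
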
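"""Domain types for administrative-claims cohorts and their CSV readers/writers.

A cohort is a set of :class:`PatientRecord` objects (each bundling one
subject's dated physician claims, hospital/ER records and drug claims) plus a
:class:`ReferenceLabel` per patient giving the chart-review disease status.
Cohorts round-trip through five plain CSV files (see :func:`read_cohort` /
:func:`write_cohort`).
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CodeSystem",
    "Setting",
    "DrugClass",
    "Sex",
    "RAStatus",
    "ReferenceMode",
    "DiagnosisCode",
    "PhysicianClaim",
    "HospitalRecord",
    "DrugClaim",
    "PatientRecord",
    "ReferenceLabel",
    "CohortError",
    "SchemaError",
    "RowError",
    "read_cohort",
    "write_cohort",
    "apply_reference_definition",
    "DEFAULT_OBS_START",
    "DEFAULT_OBS_END",
    "DEFAULT_INDEX_DATE",
]

#: Default observation window for administrative data availability.
DEFAULT_OBS_START = dt.date(1991, 4, 1)
DEFAULT_OBS_END = dt.date(2011, 3, 31)

#: Default index date at which patient age is evaluated.
DEFAULT_INDEX_DATE = dt.date(2010, 12, 31)


class CodeSystem(str, enum.Enum):
    """Coding system of a diagnosis code; determines matching semantics."""

    OHIP_DX = "OHIP_DX"
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class Setting(str, enum.Enum):
    INPATIENT = "INPATIENT"
    ER = "ER"


class DrugClass(str, enum.Enum):
    DMARD = "DMARD"
    BIOLOGIC = "BIOLOGIC"
    GLUCOCORTICOSTEROID = "GLUCOCORTICOSTEROID"
    NSAID_COXIB = "NSAID_COXIB"
    OTHER = "OTHER"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class RAStatus(str, enum.Enum):
    DEFINITE_RA = "DEFINITE_RA"
    POSSIBLE_RA = "POSSIBLE_RA"
    NON_RA = "NON_RA"


class ReferenceMode(str, enum.Enum):
    """How possible cases are regrouped when binarising reference labels."""

    DEFINITE_ONLY = "DEFINITE_ONLY"
    DEFINITE_PLUS_POSSIBLE = "DEFINITE_PLUS_POSSIBLE"


class CohortError(Exception):
    """Base class for cohort data problems."""


class SchemaError(CohortError):
    """A required column is missing or a file has the wrong shape."""


class RowError(CohortError):
    """A single row violates an invariant (bad date, unknown id, ...)."""


@dataclass(frozen=True)
class DiagnosisCode:
    value: str
    system: CodeSystem

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("diagnosis code value must be non-empty")


@dataclass(frozen=True)
class PhysicianClaim:
    """One billing claim: exactly one diagnosis code per claim."""

    service_date: dt.date
    dx: DiagnosisCode
    specialty: str


@dataclass(frozen=True)
class HospitalRecord:
    """One hospital or ER encounter with a multi-position diagnosis list."""

    event_date: dt.date
    dx_list: tuple[DiagnosisCode, ...]
    setting: Setting

    def __post_init__(self) -> None:
        if not self.dx_list:
            raise ValueError("hospital record must carry at least one diagnosis")
        # 16-position cap applies to pure ICD-9 records, 25 once ICD-10 appears
        cap = 16 if all(c.system == CodeSystem.ICD9 for c in self.dx_list) else 25
        if len(self.dx_list) > cap:
            raise ValueError(
                f"hospital record has {len(self.dx_list)} diagnoses (cap {cap})"
            )


@dataclass(frozen=True)
class DrugClaim:
    dispense_date: dt.date
    drug_class: DrugClass


@dataclass
class PatientRecord:
    """All administrative events for one subject within an observation window."""

    patient_id: str
    birth_date: dt.date
    sex: Sex
    claims: list[PhysicianClaim] = field(default_factory=list)
    hospital: list[HospitalRecord] = field(default_factory=list)
    drugs: list[DrugClaim] = field(default_factory=list)
    obs_start: dt.date = DEFAULT_OBS_START
    obs_end: dt.date = DEFAULT_OBS_END

    def age_at(self, index_date: dt.date = DEFAULT_INDEX_DATE) -> int:
        """Completed years of age at ``index_date``."""
        born = self.birth_date
        years = index_date.year - born.year
        if (index_date.month, index_date.day) < (born.month, born.day):
            years -= 1
        return years

    def event_dates(self) -> list[dt.date]:
        return (
            [c.service_date for c in self.claims]
            + [h.event_date for h in self.hospital]
            + [d.dispense_date for d in self.drugs]
        )

    def validate(self) -> None:
        """Raise :class:`RowError` if any event falls outside the window."""
        for d in self.event_dates():
            if not (self.obs_start <= d <= self.obs_end):
                raise RowError(
                    f"patient {self.patient_id}: event date {d} outside "
                    f"observation window [{self.obs_start}, {self.obs_end}]"
                )

    def shifted(self, days: int) -> "PatientRecord":
        """Copy with every event date translated by ``days`` (testing aid)."""
        delta = dt.timedelta(days=days)
        return replace(
            self,
            claims=[replace(c, service_date=c.service_date + delta) for c in self.claims],
            hospital=[replace(h, event_date=h.event_date + delta) for h in self.hospital],
            drugs=[replace(d, dispense_date=d.dispense_date + delta) for d in self.drugs],
        )


@dataclass(frozen=True)
class ReferenceLabel:
    patient_id: str
    status: RAStatus


# ---------------------------------------------------------------------------
# CSV schemas


PATIENTS_COLS = ["patient_id", "birth_date", "sex"]
CLAIMS_COLS = ["patient_id", "service_date", "dx_code", "dx_system", "specialty"]
HOSPITAL_COLS = ["patient_id", "event_date", "setting", "dx_codes", "dx_system"]
DRUGS_COLS = ["patient_id", "dispense_date", "drug_class"]
LABELS_COLS = ["patient_id", "status"]

_FILES = {
    "patients": PATIENTS_COLS,
    "physician_claims": CLAIMS_COLS,
    "hospital_records": HOSPITAL_COLS,
    "drug_claims": DRUGS_COLS,
    "labels": LABELS_COLS,
}


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    return df


def _parse_date(value: str, path: str, idx: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise RowError(f"{path} row {idx}: unparseable date {value!r}") from exc


def _parse_enum(enum_cls, value: str, path: str, idx: int):
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise RowError(
            f"{path} row {idx}: {value!r} is not a valid {enum_cls.__name__}"
        ) from exc


def read_cohort(
    directory: str | Path,
    obs_start: dt.date = DEFAULT_OBS_START,
    obs_end: dt.date = DEFAULT_OBS_END,
) -> tuple[list[PatientRecord], list[ReferenceLabel]]:
    """Load the five cohort CSVs from ``directory``.

    Every event row is attached to exactly one patient; rows referencing
    unknown patient ids, rows with unparseable dates, and events outside the
    observation window are load-time errors rather than silent drops.
    """
    directory = Path(directory)
    tables = {
        name: _read_table(directory / f"{name}.csv", cols)
        for name, cols in _FILES.items()
    }

    records: dict[str, PatientRecord] = {}
    pdf = tables["patients"]
    for idx, row in enumerate(pdf.itertuples(index=False)):
        pid = row.patient_id
        if pid in records:
            raise RowError(f"patients.csv row {idx}: duplicate patient_id {pid!r}")
        records[pid] = PatientRecord(
            patient_id=pid,
            birth_date=_parse_date(row.birth_date, "patients.csv", idx),
            sex=_parse_enum(Sex, row.sex, "patients.csv", idx),
            obs_start=obs_start,
            obs_end=obs_end,
        )

    def _owner(pid: str, path: str, idx: int) -> PatientRecord:
        try:
            return records[pid]
        except KeyError:
            raise RowError(f"{path} row {idx}: unknown patient_id {pid!r}") from None

    for idx, row in enumerate(tables["physician_claims"].itertuples(index=False)):
        rec = _owner(row.patient_id, "physician_claims.csv", idx)
        rec.claims.append(
            PhysicianClaim(
                service_date=_parse_date(row.service_date, "physician_claims.csv", idx),
                dx=DiagnosisCode(
                    row.dx_code,
                    _parse_enum(CodeSystem, row.dx_system, "physician_claims.csv", idx),
                ),
                specialty=row.specialty,
            )
        )

    for idx, row in enumerate(tables["hospital_records"].itertuples(index=False)):
        rec = _owner(row.patient_id, "hospital_records.csv", idx)
        system = _parse_enum(CodeSystem, row.dx_system, "hospital_records.csv", idx)
        codes = tuple(
            DiagnosisCode(c.strip(), system)
            for c in row.dx_codes.split(";")
            if c.strip()
        )
        if not codes:
            raise RowError(f"hospital_records.csv row {idx}: empty dx_codes")
        rec.hospital.append(
            HospitalRecord(
                event_date=_parse_date(row.event_date, "hospital_records.csv", idx),
                dx_list=codes,
                setting=_parse_enum(Setting, row.setting, "hospital_records.csv", idx),
            )
        )

    for idx, row in enumerate(tables["drug_claims"].itertuples(index=False)):
        rec = _owner(row.patient_id, "drug_claims.csv", idx)
        rec.drugs.append(
            DrugClaim(
                dispense_date=_parse_date(row.dispense_date, "drug_claims.csv", idx),
                drug_class=_parse_enum(DrugClass, row.drug_class, "drug_claims.csv", idx),
            )
        )

    labels: list[ReferenceLabel] = []
    seen: set[str] = set()
    for idx, row in enumerate(tables["labels"].itertuples(index=False)):
        _owner(row.patient_id, "labels.csv", idx)
        if row.patient_id in seen:
            raise RowError(f"labels.csv row {idx}: duplicate label for {row.patient_id!r}")
        seen.add(row.patient_id)
        labels.append(
            ReferenceLabel(
                patient_id=row.patient_id,
                status=_parse_enum(RAStatus, row.status, "labels.csv", idx),
            )
        )
    unlabeled = set(records) - seen
    if unlabeled:
        raise RowError(f"patients without a reference label: {sorted(unlabeled)[:5]}")

    for rec in records.values():
        rec.validate()

    return list(records.values()), labels


def write_cohort(
    records: Iterable[PatientRecord],
    labels: Iterable[ReferenceLabel],
    directory: str | Path,
) -> None:
    """Write the five cohort CSVs. Output is sorted and byte-deterministic."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    recs = sorted(records, key=lambda r: r.patient_id)
    pd.DataFrame(
        [(r.patient_id, r.birth_date.isoformat(), r.sex.value) for r in recs],
        columns=PATIENTS_COLS,
    ).to_csv(directory / "patients.csv", index=False)

    claims = sorted(
        (
            (r.patient_id, c.service_date.isoformat(), c.dx.value, c.dx.system.value, c.specialty)
            for r in recs
            for c in r.claims
        )
    )
    pd.DataFrame(claims, columns=CLAIMS_COLS).to_csv(
        directory / "physician_claims.csv", index=False
    )

    hosp = sorted(
        (
            (
                r.patient_id,
                h.event_date.isoformat(),
                h.setting.value,
                ";".join(c.value for c in h.dx_list),
                h.dx_list[0].system.value,
            )
            for r in recs
            for h in r.hospital
        )
    )
    pd.DataFrame(hosp, columns=HOSPITAL_COLS).to_csv(
        directory / "hospital_records.csv", index=False
    )

    drugs = sorted(
        (
            (r.patient_id, d.dispense_date.isoformat(), d.drug_class.value)
            for r in recs
            for d in r.drugs
        )
    )
    pd.DataFrame(drugs, columns=DRUGS_COLS).to_csv(
        directory / "drug_claims.csv", index=False
    )

    pd.DataFrame(
        sorted((l.patient_id, l.status.value) for l in labels),
        columns=LABELS_COLS,
    ).to_csv(directory / "labels.csv", index=False)


def apply_reference_definition(
    labels: Iterable[ReferenceLabel],
    mode: ReferenceMode,
) -> dict[str, bool]:
    """Binarise reference labels under the given regrouping mode.

    DEFINITE_ONLY maps POSSIBLE_RA to non-case; DEFINITE_PLUS_POSSIBLE maps it
    to case. NON_RA is always a non-case.
    """
    mode = ReferenceMode(mode)
    out: dict[str, bool] = {}
    for label in labels:
        if label.patient_id in out:
            raise RowError(f"duplicate patient_id in labels: {label.patient_id!r}")
        if label.status == RAStatus.DEFINITE_RA:
            case = True
        elif label.status == RAStatus.POSSIBLE_RA:
            case = mode == ReferenceMode.DEFINITE_PLUS_POSSIBLE
        else:
            case = False
        out[label.patient_id] = case
    return out
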
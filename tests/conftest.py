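from __future__ import annotations

import datetime as dt
import json

import numpy as np
import pytest

from claimcase import data_path
from claimcase.codesets import CodeConfig
from claimcase.engine import parse_algorithm_spec
from claimcase.model import (
    CodeSystem,
    DiagnosisCode,
    DrugClaim,
    DrugClass,
    HospitalRecord,
    PatientRecord,
    PhysicianClaim,
    Setting,
    Sex,
)

DAY0 = dt.date(1995, 1, 1)


@pytest.fixture(scope="session")
def config() -> CodeConfig:
    return CodeConfig()


@pytest.fixture(scope="session")
def fixture_algorithms():
    """The 43 bundled algorithm specs, parsed."""
    with open(data_path("algorithms.json")) as fh:
        raw = json.load(fh)
    return [
        (parse_algorithm_spec(a["dsl"], a["algorithm_id"]), a.get("age_subset"))
        for a in raw
    ]


def d(day: int) -> dt.date:
    """Day offset relative to a fixed anchor inside the observation window."""
    return DAY0 + dt.timedelta(days=day)


def claim(day: int, code: str = "714", specialty: str = "family medicine",
          system: CodeSystem = CodeSystem.OHIP_DX) -> PhysicianClaim:
    return PhysicianClaim(
        service_date=d(day), dx=DiagnosisCode(code, system), specialty=specialty
    )


def hosp(day: int, codes, setting: Setting = Setting.INPATIENT,
         system: CodeSystem = CodeSystem.ICD9) -> HospitalRecord:
    return HospitalRecord(
        event_date=d(day),
        dx_list=tuple(DiagnosisCode(c, system) for c in codes),
        setting=setting,
    )


def rx(day: int, drug_class: DrugClass = DrugClass.DMARD) -> DrugClaim:
    return DrugClaim(dispense_date=d(day), drug_class=drug_class)


def make_patient(claims=(), hospital=(), drugs=(), age: int = 70,
                 patient_id: str = "X") -> PatientRecord:
    birth = dt.date(2010, 12, 31) - dt.timedelta(days=int(age * 365.25) + 1)
    return PatientRecord(
        patient_id=patient_id,
        birth_date=birth,
        sex=Sex.F,
        claims=list(claims),
        hospital=list(hospital),
        drugs=list(drugs),
    )


# -- random small patients, used by the engine-vs-oracle suites -------------

_CODE_POOL = [
    ("714", CodeSystem.OHIP_DX), ("714", CodeSystem.OHIP_DX),  # RA, overweighted
    ("715", CodeSystem.OHIP_DX), ("274", CodeSystem.OHIP_DX),  # other rheum
    ("250", CodeSystem.OHIP_DX), ("401", CodeSystem.OHIP_DX),  # other
]
_SPECIALTIES = [
    "family medicine", "family medicine", "rheumatology",
    "orthopedic surgery", "internal medicine",
]
_HOSP_CODES = [["714", "428"], ["M05.9"], ["250", "401"], ["M06.1", "I50"]]
_DRUGS = [DrugClass.DMARD, DrugClass.BIOLOGIC, DrugClass.GLUCOCORTICOSTEROID,
          DrugClass.NSAID_COXIB]


def random_patient(rng: np.random.Generator, max_events: int = 12) -> PatientRecord:
    """A random small patient with at most ``max_events`` events total."""
    budget = int(rng.integers(0, max_events + 1))
    n_claims = int(rng.integers(0, budget + 1))
    n_hosp = int(rng.integers(0, budget - n_claims + 1))
    n_rx = budget - n_claims - n_hosp
    claims = []
    for _ in range(n_claims):
        code, system = _CODE_POOL[int(rng.integers(0, len(_CODE_POOL)))]
        claims.append(
            claim(
                int(rng.integers(0, 2000)),
                code,
                _SPECIALTIES[int(rng.integers(0, len(_SPECIALTIES)))],
                system,
            )
        )
    hospital = []
    for _ in range(n_hosp):
        codes = _HOSP_CODES[int(rng.integers(0, len(_HOSP_CODES)))]
        system = CodeSystem.ICD10 if any(c.startswith("M") or c.startswith("I") for c in codes) else CodeSystem.ICD9
        hospital.append(
            hosp(
                int(rng.integers(0, 2000)),
                codes,
                Setting.INPATIENT if rng.random() < 0.6 else Setting.ER,
                system,
            )
        )
    drugs = [
        rx(int(rng.integers(0, 2000)), _DRUGS[int(rng.integers(0, len(_DRUGS)))])
        for _ in range(n_rx)
    ]
    age = int(rng.integers(20, 95))
    return make_patient(claims, hospital, drugs, age=age)
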
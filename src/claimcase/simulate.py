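"""Seeded synthetic claims cohorts with the marginal structure the
evaluation pipeline assumes.

Cases follow a two-phase history: an active-care episode emitting frequent
RA-coded physician visits (specialist-coded for most patients), followed by
quiescence with sparse coding — so lifetime-diagnosis cases that are no
longer under active care exist. Non-cases receive background visits with
unrelated (and occasionally other-rheumatology) codes, plus a small chance of
RA miscoding that produces false positives. Possible (borderline) cases are
weakly coded streams with no specialist confirmation.

All sampling comes from a single explicitly seeded numpy Generator; identical
parameters and seed give byte-identical CSV output through
:func:`claimcase.model.write_cohort`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np

from .codesets import CodeConfig, CodeClass, classify_code, default_code_config
from .model import (
    DEFAULT_INDEX_DATE,
    DEFAULT_OBS_END,
    DEFAULT_OBS_START,
    CodeSystem,
    DiagnosisCode,
    DrugClaim,
    DrugClass,
    HospitalRecord,
    PatientRecord,
    PhysicianClaim,
    RAStatus,
    ReferenceLabel,
    Setting,
    Sex,
)

__all__ = ["CohortParams", "generate_cohort", "planted_truth_report"]

_ICD10_CUTOVER = dt.date(2002, 4, 1)

_OTHER_CODES = ("250", "401", "780", "460", "786", "724")
_OTHER_RHEUM_CODES = ("715", "274", "725")
_NONSPEC_SPECIALTIES = ("family medicine", "general practice")
_MSK_SPECIALTIES = ("rheumatology", "orthopedic surgery", "internal medicine")


@dataclass
class CohortParams:
    """Distributional knobs of the generator; defaults reproduce the
    published marginal scales (prevalence, coded fractions, drug exposure)."""

    n_adults: int = 7500
    n_seniors_extra: int = 2000
    prev_adult: float = 0.009
    prev_senior: float = 0.018
    possible_ra_fraction: float = 0.004
    p_specialist_care: float = 0.86
    visit_rate_case: float = 4.0       # RA-coded visits/year during active care
    quiescent_rate: float = 0.15       # RA-coded visits/year after the episode
    p_case_ever_coded: float = 0.90
    p_noncase_ever_coded: float = 0.033
    p_case_hosp: float = 0.22
    p_case_er: float = 0.05
    p_dmard: float = 0.80
    p_glucocorticosteroid: float = 0.61
    p_biologic: float = 0.17
    p_nsaid: float = 0.77
    p_female_case: float = 0.64
    p_female_noncase: float = 0.52
    # non-case nuisance processes
    background_visit_rate: float = 0.8   # non-RA visits/year, everyone
    p_noncase_other_rheum: float = 0.25
    p_noncase_rheum_visit: float = 0.02
    miscode_extra_mean: float = 0.35     # Poisson mean of miscodes beyond the first
    p_miscode_specialist: float = 0.15
    p_noncase_hosp_ra: float = 0.00027
    p_noncase_er_ra: float = 0.00027
    noncase_senior_gc: float = 0.25
    noncase_senior_dmard: float = 0.01
    noncase_senior_nsaid: float = 0.35
    miscoded_senior_gc: float = 0.60
    p_possible_coded: float = 0.5
    seed: int = 0
    obs_start: dt.date = DEFAULT_OBS_START
    obs_end: dt.date = DEFAULT_OBS_END
    index_date: dt.date = DEFAULT_INDEX_DATE

    def validate(self) -> None:
        if self.n_adults < 1:
            raise ValueError("n_adults must be >= 1")
        if self.n_seniors_extra < 0:
            raise ValueError("n_seniors_extra must be >= 0")
        for f in fields(self):
            if f.name.startswith(("p_", "prev_")) or f.name in (
                "possible_ra_fraction",
                "noncase_senior_gc",
                "noncase_senior_dmard",
                "noncase_senior_nsaid",
                "miscoded_senior_gc",
            ):
                v = getattr(self, f.name)
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{f.name}={v} is not a probability")
        if self.obs_start >= self.obs_end:
            raise ValueError("obs_start must precede obs_end")


def _date_in(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _ra_code(date: dt.date) -> DiagnosisCode:
    return DiagnosisCode("714", CodeSystem.OHIP_DX)


def _hospital_ra_record(rng: np.random.Generator, date: dt.date, setting: Setting) -> HospitalRecord:
    if date < _ICD10_CUTOVER:
        system, ra = CodeSystem.ICD9, "714"
        pool = ("428", "250", "486", "410")
    else:
        system, ra = CodeSystem.ICD10, ("M05.9", "M06.9")[int(rng.integers(0, 2))]
        pool = ("I50", "E11", "J18", "I21")
    n_other = int(rng.integers(0, 4))
    codes = [DiagnosisCode(ra, system)] + [
        DiagnosisCode(pool[int(rng.integers(0, len(pool)))], system)
        for _ in range(n_other)
    ]
    order = rng.permutation(len(codes))  # RA may sit in any diagnosis position
    return HospitalRecord(
        event_date=date, dx_list=tuple(codes[int(k)] for k in order), setting=setting
    )


def _background_claims(
    rng: np.random.Generator,
    params: CohortParams,
    other_rheum: bool,
) -> list[PhysicianClaim]:
    years = (params.obs_end - params.obs_start).days / 365.25
    n = int(rng.poisson(params.background_visit_rate * years))
    claims = []
    for _ in range(n):
        date = _date_in(rng, params.obs_start, params.obs_end)
        if other_rheum and rng.random() < 0.15:
            code = _OTHER_RHEUM_CODES[int(rng.integers(0, len(_OTHER_RHEUM_CODES)))]
        else:
            code = _OTHER_CODES[int(rng.integers(0, len(_OTHER_CODES)))]
        claims.append(
            PhysicianClaim(
                service_date=date,
                dx=DiagnosisCode(code, CodeSystem.OHIP_DX),
                specialty=_NONSPEC_SPECIALTIES[int(rng.integers(0, 2))],
            )
        )
    return claims


def _case_stream(
    rng: np.random.Generator, params: CohortParams, senior: bool, weak: bool
) -> tuple[list[PhysicianClaim], list[HospitalRecord], list[DrugClaim]]:
    """Event streams for a definite (or, with ``weak``, possible) case."""
    claims: list[PhysicianClaim] = []
    hospital: list[HospitalRecord] = []
    drugs: list[DrugClaim] = []

    onset = _date_in(rng, params.obs_start, params.obs_end - dt.timedelta(days=365))
    active_years = float(rng.uniform(2.0, 8.0)) if not weak else float(rng.uniform(0.5, 1.5))
    episode_end = min(
        params.obs_end, onset + dt.timedelta(days=int(active_years * 365.25))
    )

    coded = rng.random() < (
        params.p_possible_coded if weak else params.p_case_ever_coded
    )
    if coded:
        years = max((episode_end - onset).days / 365.25, 0.1)
        if weak:
            n_visits = 1 + int(rng.integers(0, 2))
        else:
            n_visits = 1 + int(rng.poisson(params.visit_rate_case * years))
        visit_dates = sorted(_date_in(rng, onset, episode_end) for _ in range(n_visits))
        has_specialist = (not weak) and rng.random() < params.p_specialist_care
        spec_flags = [has_specialist and rng.random() < 0.5 for _ in visit_dates]
        if has_specialist and not any(spec_flags):
            spec_flags[0] = True
        for date, is_spec in zip(visit_dates, spec_flags):
            if is_spec:
                specialty = _MSK_SPECIALTIES[
                    0 if rng.random() < 0.7 else int(rng.integers(1, 3))
                ]
            else:
                specialty = _NONSPEC_SPECIALTIES[int(rng.integers(0, 2))]
            claims.append(
                PhysicianClaim(service_date=date, dx=_ra_code(date), specialty=specialty)
            )
        # quiescent phase: sparse RA coding until the end of observation
        if not weak and episode_end < params.obs_end:
            quiet_years = (params.obs_end - episode_end).days / 365.25
            for _ in range(int(rng.poisson(params.quiescent_rate * quiet_years))):
                date = _date_in(rng, episode_end, params.obs_end)
                claims.append(
                    PhysicianClaim(
                        service_date=date,
                        dx=_ra_code(date),
                        specialty=_NONSPEC_SPECIALTIES[int(rng.integers(0, 2))],
                    )
                )

    if not weak and rng.random() < params.p_case_hosp:
        hospital.append(
            _hospital_ra_record(rng, _date_in(rng, onset, episode_end), Setting.INPATIENT)
        )
    if not weak and rng.random() < params.p_case_er:
        hospital.append(
            _hospital_ra_record(rng, _date_in(rng, onset, episode_end), Setting.ER)
        )

    if senior:
        exposures = (
            (DrugClass.DMARD, params.p_dmard),
            (DrugClass.GLUCOCORTICOSTEROID, params.p_glucocorticosteroid),
            (DrugClass.BIOLOGIC, params.p_biologic),
            (DrugClass.NSAID_COXIB, params.p_nsaid),
        )
        for drug_class, prob in exposures:
            if weak and drug_class in (DrugClass.DMARD, DrugClass.BIOLOGIC):
                continue  # borderline cases lack definitive RA therapy
            if rng.random() < prob:
                for _ in range(1 + int(rng.poisson(3.0))):
                    drugs.append(
                        DrugClaim(
                            dispense_date=_date_in(rng, onset, episode_end),
                            drug_class=drug_class,
                        )
                    )

    return claims, hospital, drugs


def _noncase_stream(
    rng: np.random.Generator, params: CohortParams, senior: bool
) -> tuple[list[PhysicianClaim], list[HospitalRecord], list[DrugClaim]]:
    other_rheum = rng.random() < params.p_noncase_other_rheum
    claims = _background_claims(rng, params, other_rheum)
    hospital: list[HospitalRecord] = []
    drugs: list[DrugClaim] = []

    miscoded = rng.random() < params.p_noncase_ever_coded
    if miscoded:
        k = 1 + int(rng.poisson(params.miscode_extra_mean))
        first = _date_in(rng, params.obs_start, params.obs_end - dt.timedelta(days=300))
        dates = [first] + [
            first + dt.timedelta(days=int(rng.integers(1, 301))) for _ in range(k - 1)
        ]
        for date in dates:
            if rng.random() < params.p_miscode_specialist:
                specialty = _MSK_SPECIALTIES[int(rng.integers(0, 3))]
            else:
                specialty = _NONSPEC_SPECIALTIES[int(rng.integers(0, 2))]
            claims.append(
                PhysicianClaim(service_date=date, dx=_ra_code(date), specialty=specialty)
            )

    if rng.random() < params.p_noncase_rheum_visit:
        date = _date_in(rng, params.obs_start, params.obs_end)
        claims.append(
            PhysicianClaim(
                service_date=date,
                dx=DiagnosisCode(
                    _OTHER_RHEUM_CODES[int(rng.integers(0, 3))], CodeSystem.OHIP_DX
                ),
                specialty="rheumatology",
            )
        )

    if rng.random() < params.p_noncase_hosp_ra:
        hospital.append(
            _hospital_ra_record(
                rng, _date_in(rng, params.obs_start, params.obs_end), Setting.INPATIENT
            )
        )
    if rng.random() < params.p_noncase_er_ra:
        hospital.append(
            _hospital_ra_record(
                rng, _date_in(rng, params.obs_start, params.obs_end), Setting.ER
            )
        )

    if senior:
        p_gc = params.miscoded_senior_gc if miscoded else params.noncase_senior_gc
        for drug_class, prob in (
            (DrugClass.GLUCOCORTICOSTEROID, p_gc),
            (DrugClass.DMARD, params.noncase_senior_dmard),
            (DrugClass.NSAID_COXIB, params.noncase_senior_nsaid),
        ):
            if rng.random() < prob:
                drugs.append(
                    DrugClaim(
                        dispense_date=_date_in(rng, params.obs_start, params.obs_end),
                        drug_class=drug_class,
                    )
                )

    return claims, hospital, drugs


def _draw_age(rng: np.random.Generator, senior_stratum: bool) -> float:
    if senior_stratum:
        return min(100.0, 65.0 + float(rng.gamma(1.6, 7.0)))
    return min(98.0, 20.0 + float(rng.gamma(2.2, 13.0)))


def generate_cohort(
    params: CohortParams | None = None,
) -> tuple[list[PatientRecord], list[ReferenceLabel]]:
    """Generate one cohort: ``n_adults`` from the adult stratum (ages >=20)
    plus ``n_seniors_extra`` from the senior stratum (ages >=65)."""
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    records: list[PatientRecord] = []
    labels: list[ReferenceLabel] = []
    total = params.n_adults + params.n_seniors_extra
    width = max(6, len(str(total)))

    for i in range(total):
        senior_stratum = i >= params.n_adults
        age = _draw_age(rng, senior_stratum)
        senior = age >= 65
        birth = params.index_date - dt.timedelta(days=int(age * 365.25))

        prev = params.prev_senior if senior else params.prev_adult
        u = rng.random()
        if u < prev:
            status = RAStatus.DEFINITE_RA
        elif u < prev + params.possible_ra_fraction:
            status = RAStatus.POSSIBLE_RA
        else:
            status = RAStatus.NON_RA

        if status == RAStatus.NON_RA:
            sex = Sex.F if rng.random() < params.p_female_noncase else Sex.M
            claims, hospital, drugs = _noncase_stream(rng, params, senior)
        else:
            sex = Sex.F if rng.random() < params.p_female_case else Sex.M
            claims, hospital, drugs = _case_stream(
                rng, params, senior, weak=(status == RAStatus.POSSIBLE_RA)
            )
            claims.extend(_background_claims(rng, params, other_rheum=False))

        pid = f"PT{i:0{width}d}"
        records.append(
            PatientRecord(
                patient_id=pid,
                birth_date=birth,
                sex=sex,
                claims=sorted(claims, key=lambda c: (c.service_date, c.dx.value)),
                hospital=sorted(hospital, key=lambda h: h.event_date),
                drugs=sorted(drugs, key=lambda d: (d.dispense_date, d.drug_class.value)),
                obs_start=params.obs_start,
                obs_end=params.obs_end,
            )
        )
        labels.append(ReferenceLabel(patient_id=pid, status=status))

    return records, labels


def planted_truth_report(
    records: Iterable[PatientRecord],
    labels: Iterable[ReferenceLabel],
    config: CodeConfig | None = None,
    index_date: dt.date = DEFAULT_INDEX_DATE,
) -> dict:
    """Realised marginals of a generated cohort, computed exactly from the
    event streams (for parameter-recovery checks)."""
    records = list(records)
    labels = list(labels)
    if not records:
        raise ValueError("empty cohort")
    config = config or default_code_config()
    status = {l.patient_id: l.status for l in labels}

    def has_ra_claim(rec: PatientRecord) -> bool:
        return any(classify_code(c.dx, config) is CodeClass.RA for c in rec.claims)

    cases = [r for r in records if status[r.patient_id] == RAStatus.DEFINITE_RA]
    noncases = [r for r in records if status[r.patient_id] == RAStatus.NON_RA]
    seniors = [r for r in records if r.age_at(index_date) >= 65]
    senior_cases = [r for r in cases if r.age_at(index_date) >= 65]

    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    def drug_rate(pop: list[PatientRecord], drug_class: DrugClass) -> float | None:
        return frac(
            sum(any(d.drug_class == drug_class for d in r.drugs) for r in pop),
            len(pop),
        )

    return {
        "n_patients": len(records),
        "n_cases": len(cases),
        "n_seniors": len(seniors),
        "prevalence": frac(len(cases), len(records)),
        "prevalence_seniors": frac(len(senior_cases), len(seniors)),
        "case_ever_coded": frac(sum(map(has_ra_claim, cases)), len(cases)),
        "noncase_ever_coded": frac(sum(map(has_ra_claim, noncases)), len(noncases)),
        "case_hospitalized": frac(
            sum(
                any(s.setting == Setting.INPATIENT for s in r.hospital) for r in cases
            ),
            len(cases),
        ),
        "senior_case_dmard": drug_rate(senior_cases, DrugClass.DMARD),
        "senior_case_glucocorticosteroid": drug_rate(
            senior_cases, DrugClass.GLUCOCORTICOSTEROID
        ),
        "senior_case_biologic": drug_rate(senior_cases, DrugClass.BIOLOGIC),
    }
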
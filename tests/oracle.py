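"""Independent brute-force oracle for algorithm evaluation.

Deliberately shares no window/chain logic with claimcase.engine: clauses are
checked by exhaustive enumeration of date subsets with itertools. Only usable
for small patients (the acceptance suite caps events per patient at 12).
"""

from __future__ import annotations

import datetime as dt
from itertools import combinations

from claimcase.codesets import CodeClass, CodeConfig, classify_code, is_msk_specialist
from claimcase.engine import EVER, AlgorithmSpec, Clause, ExclusionRule, Source
from claimcase.model import DEFAULT_INDEX_DATE, PatientRecord, Setting


def _ra_physician_entries(patient: PatientRecord, config: CodeConfig):
    by_date: dict[dt.date, bool] = {}
    for c in patient.claims:
        if classify_code(c.dx, config) is CodeClass.RA:
            spec = is_msk_specialist(c.specialty, config)
            by_date[c.service_date] = by_date.get(c.service_date, False) or spec
    return sorted(by_date.items())


def _hospital_dates(patient: PatientRecord, setting: Setting, config: CodeConfig):
    return sorted(
        {
            h.event_date
            for h in patient.hospital
            if h.setting == setting
            and any(classify_code(c, config) is CodeClass.RA for c in h.dx_list)
        }
    )


def _subset_ok(subset, window_days, min_gap_days, require_specialist) -> bool:
    dates = [d for d, _ in subset]
    if window_days is not EVER and (dates[-1] - dates[0]).days > window_days:
        return False
    for a, b in zip(dates, dates[1:]):
        if (b - a).days < min_gap_days:
            return False
    if require_specialist and not any(f for _, f in subset):
        return False
    return True


def clause_holds(
    clause: Clause,
    patient: PatientRecord,
    config: CodeConfig,
    index_date: dt.date = DEFAULT_INDEX_DATE,
) -> bool:
    if clause.require_rx and patient.age_at(index_date) < 65:
        return False
    if clause.source is Source.PHYSICIAN:
        entries = _ra_physician_entries(patient, config)
    else:
        setting = Setting.INPATIENT if clause.source is Source.HOSPITAL else Setting.ER
        entries = [(d, False) for d in _hospital_dates(patient, setting, config)]

    rx_dates = [
        d.dispense_date for d in patient.drugs if d.drug_class in clause.rx_classes
    ]
    for subset in combinations(entries, clause.n_codes):
        if not _subset_ok(
            subset, clause.window_days, clause.min_gap_days, clause.require_specialist
        ):
            continue
        if not clause.require_rx:
            return True
        if clause.window_days is EVER:
            if rx_dates:
                return True
            continue
        dates = [d for d, _ in subset]
        for rx in rx_dates:
            span = (max(dates + [rx]) - min(dates + [rx])).days
            if span <= clause.window_days:
                return True
    return False


def exclusion_holds(
    patient: PatientRecord, rule: ExclusionRule, config: CodeConfig
) -> bool:
    ra = [
        c.service_date
        for c in patient.claims
        if classify_code(c.dx, config) is CodeClass.RA
    ]
    if rule.case_a and ra:
        last = max(ra)
        if any(
            c.service_date > last
            and classify_code(c.dx, config) is CodeClass.OTHER_RHEUM
            for c in patient.claims
        ):
            return True
    if rule.case_b:
        anchor = min(ra) if ra else patient.obs_start
        if any(
            c.specialty.strip().lower() == "rheumatology"
            and c.service_date >= anchor
            and classify_code(c.dx, config) is not CodeClass.RA
            for c in patient.claims
        ):
            return True
    return False


def evaluate(
    spec: AlgorithmSpec,
    patient: PatientRecord,
    config: CodeConfig,
    index_date: dt.date = DEFAULT_INDEX_DATE,
) -> bool:
    if not any(clause_holds(c, patient, config, index_date) for c in spec.clauses):
        return False
    if spec.exclusions and exclusion_holds(patient, spec.exclusions, config):
        return False
    return True
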
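"""Case-ascertainment rule engine over per-patient claim streams.

An :class:`AlgorithmSpec` is an OR of :class:`Clause` objects plus an optional
:class:`ExclusionRule`. A physician clause counts distinct RA-coded service
dates inside a sliding window, with optional minimum gaps between consecutive
counted dates, an optional requirement that at least one counted date carry a
musculoskeletal-specialist billing, and an optional co-occurring drug claim.
Hospital/ER clauses accept an RA code in any diagnosis position.

Specs are expressed in a small text grammar (see :func:`parse_algorithm_spec`)::

    algorithm := clause (" | " clause)* [" excl(" flags ")"]
    clause    := COUNT SOURCE ["(" mod ("," mod)* ")"] ["/" WINDOW]
    SOURCE    := "P" | "H" | "E"            (physician / hospital / ER)
    mod       := "gap>=" DAYS "d" | "spec>=1" | "rx>=1"
    WINDOW    := YEARS "y" | DAYS "d"       (absent = ever)
    flags     := "A" | "B" | "A,B"

Examples: ``"1H"``, ``"3P(spec>=1)/2y"``, ``"1H | 2P(gap>=56d)/2y excl(A,B)"``.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
import warnings
from dataclasses import dataclass, field

from .codesets import CodeClass, CodeConfig, classify_code, is_msk_specialist
from .model import (
    DEFAULT_INDEX_DATE,
    DrugClass,
    PatientRecord,
    Setting,
)

__all__ = [
    "EVER",
    "Source",
    "Clause",
    "ExclusionRule",
    "AlgorithmSpec",
    "DslError",
    "qualifying_physician_dates",
    "hospital_ra_ever",
    "window_satisfied",
    "rx_satisfied",
    "exclusion_triggered",
    "evaluate_algorithm",
    "parse_algorithm_spec",
    "render_algorithm_spec",
]

#: Sentinel window meaning "anytime in the observation period".
EVER = None

DEFAULT_RX_CLASSES = frozenset(
    {DrugClass.DMARD, DrugClass.BIOLOGIC, DrugClass.GLUCOCORTICOSTEROID}
)

#: Minimum age (at the index date) for drug-requiring clauses; pharmacy
#: claims are only observed for seniors.
RX_MIN_AGE = 65


class Source(str, enum.Enum):
    PHYSICIAN = "PHYSICIAN"
    HOSPITAL = "HOSPITAL"
    ER = "ER"


class DslError(ValueError):
    """Syntax error in the algorithm grammar, with position information."""

    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Clause:
    source: Source
    n_codes: int
    window_days: int | None = EVER
    min_gap_days: int = 0
    require_specialist: bool = False
    require_rx: bool = False
    rx_classes: frozenset[DrugClass] = DEFAULT_RX_CLASSES

    def __post_init__(self) -> None:
        if self.n_codes < 1:
            raise ValueError("n_codes must be >= 1")
        if self.window_days is not EVER and self.window_days < 1:
            raise ValueError("window_days must be positive (or EVER)")
        if self.min_gap_days < 0:
            raise ValueError("min_gap_days must be non-negative")
        if self.source is not Source.PHYSICIAN and (
            self.require_specialist or self.require_rx or self.min_gap_days
        ):
            raise ValueError(
                "specialist/rx/gap modifiers apply to physician clauses only"
            )
        if (
            self.window_days is not EVER
            and self.window_days < self.min_gap_days * (self.n_codes - 1)
        ):
            warnings.warn(
                f"clause unsatisfiable: window {self.window_days}d cannot hold "
                f"{self.n_codes} dates {self.min_gap_days}d apart",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ExclusionRule:
    case_a: bool = False  # other-rheum code after the last RA code
    case_b: bool = False  # rheumatologist visit without an RA code

    def __bool__(self) -> bool:
        return self.case_a or self.case_b


@dataclass(frozen=True)
class AlgorithmSpec:
    algorithm_id: str
    clauses: tuple[Clause, ...]
    exclusions: ExclusionRule = ExclusionRule()

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("algorithm must have at least one clause")

    @property
    def requires_rx(self) -> bool:
        return any(c.require_rx for c in self.clauses)


# ---------------------------------------------------------------------------
# Event extraction


def qualifying_physician_dates(
    patient: PatientRecord,
    config: CodeConfig,
    count_same_day: bool = False,
) -> list[tuple[dt.date, bool]]:
    """Distinct service dates with >=1 RA-coded physician claim, ascending.

    The flag is true iff at least one RA claim on that date carries a
    musculoskeletal specialty. With ``count_same_day`` duplicates are kept
    (sensitivity-analysis switch); by default same-day claims collapse to one
    qualifying date.
    """
    by_date: dict[dt.date, bool] = {}
    multiplicity: dict[dt.date, int] = {}
    for claim in patient.claims:
        if classify_code(claim.dx, config) is not CodeClass.RA:
            continue
        spec = is_msk_specialist(claim.specialty, config)
        by_date[claim.service_date] = by_date.get(claim.service_date, False) or spec
        multiplicity[claim.service_date] = multiplicity.get(claim.service_date, 0) + 1
    out: list[tuple[dt.date, bool]] = []
    for date in sorted(by_date):
        reps = multiplicity[date] if count_same_day else 1
        out.extend([(date, by_date[date])] * reps)
    return out


def hospital_ra_dates(
    patient: PatientRecord, setting: Setting, config: CodeConfig
) -> list[dt.date]:
    """Ascending distinct dates of records (given setting) with an RA code
    in any diagnosis position."""
    dates = {
        rec.event_date
        for rec in patient.hospital
        if rec.setting == setting
        and any(classify_code(c, config) is CodeClass.RA for c in rec.dx_list)
    }
    return sorted(dates)


def hospital_ra_ever(
    patient: PatientRecord, setting: Setting, config: CodeConfig
) -> bool:
    return bool(hospital_ra_dates(patient, setting, config))


# ---------------------------------------------------------------------------
# Window logic


def _chain_table(
    dates: list[dt.date],
    flags: list[bool],
    n: int,
    min_gap_days: int,
) -> list[dict[bool, dt.date]]:
    """For each end index j, the latest achievable first-date of an n-chain
    ending at j, keyed by whether the chain contains a specialist date.

    A chain is n entries ``D_1 <= ... <= D_n`` with every consecutive pair
    separated by at least ``min_gap_days``. Maximising the first date is
    optimal for any window test anchored at the chain end.
    """
    m = len(dates)
    # best[j][s] = latest first-date over chains of current length ending at j
    # with specialist-state s; absent key = no such chain.
    best: list[dict[bool, dt.date]] = [{flags[j]: dates[j]} for j in range(m)]
    for _ in range(n - 1):
        nxt: list[dict[bool, dt.date]] = [dict() for _ in range(m)]
        for j in range(m):
            for i in range(j):
                if (dates[j] - dates[i]).days < min_gap_days:
                    continue
                for s_prev, first in best[i].items():
                    s = s_prev or flags[j]
                    if s not in nxt[j] or first > nxt[j][s]:
                        nxt[j][s] = first
        best = nxt
    return best


def window_satisfied(
    dates: list[tuple[dt.date, bool]],
    n: int,
    window_days: int | None,
    min_gap_days: int = 0,
    require_specialist: bool = False,
) -> dt.date | None:
    """Earliest date ``D_n`` completing a qualifying n-subset, or None.

    A subset qualifies when its span ``D_n - D_1`` is at most ``window_days``
    (always true under EVER), consecutive members are at least
    ``min_gap_days`` apart, and — if required — at least one member carries
    the specialist flag.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if (
        window_days is not EVER
        and window_days < min_gap_days * (n - 1)
    ):
        warnings.warn("window shorter than required gaps: unsatisfiable", stacklevel=2)
    if len(dates) < n:
        return None
    ds = [d for d, _ in dates]
    fs = [f for _, f in dates]
    best = _chain_table(ds, fs, n, min_gap_days)
    for j in range(len(ds)):
        states = [True] if require_specialist else list(best[j])
        for s in states:
            first = best[j].get(s)
            if first is None:
                continue
            if window_days is EVER or (ds[j] - first).days <= window_days:
                return ds[j]
    return None


def _rx_dates(patient: PatientRecord, rx_classes: frozenset[DrugClass]) -> list[dt.date]:
    return sorted(d.dispense_date for d in patient.drugs if d.drug_class in rx_classes)


def rx_satisfied(
    patient: PatientRecord,
    clause: Clause,
    anchor_window: tuple[dt.date, dt.date] | None = EVER,
) -> bool:
    """True iff a drug claim of an allowed class falls in ``anchor_window``
    (or anytime, under EVER)."""
    rx = _rx_dates(patient, clause.rx_classes)
    if not rx:
        return False
    if anchor_window is EVER:
        return True
    lo, hi = anchor_window
    return any(lo <= d <= hi for d in rx)


def _physician_clause_date(
    clause: Clause,
    patient: PatientRecord,
    config: CodeConfig,
    count_same_day: bool = False,
) -> dt.date | None:
    entries = qualifying_physician_dates(patient, config, count_same_day)
    if len(entries) < clause.n_codes:
        return None
    if not clause.require_rx:
        return window_satisfied(
            entries,
            clause.n_codes,
            clause.window_days,
            clause.min_gap_days,
            clause.require_specialist,
        )
    rx = _rx_dates(patient, clause.rx_classes)
    if not rx:
        return None
    if clause.window_days is EVER:
        # the drug claim may occur anytime in the observation window
        return window_satisfied(
            entries,
            clause.n_codes,
            EVER,
            clause.min_gap_days,
            clause.require_specialist,
        )
    # all required events must fit inside one interval of length window_days:
    # chain span <= W and rx in [chain_end - W, chain_start + W]
    w = dt.timedelta(days=clause.window_days)
    ds = [d for d, _ in entries]
    fs = [f for _, f in entries]
    best = _chain_table(ds, fs, clause.n_codes, clause.min_gap_days)
    for j in range(len(ds)):
        states = [True] if clause.require_specialist else list(best[j])
        for s in states:
            first = best[j].get(s)
            if first is None or (ds[j] - first) > w:
                continue
            if rx_satisfied(patient, clause, (ds[j] - w, first + w)):
                return ds[j]
    return None


def clause_satisfied(
    clause: Clause,
    patient: PatientRecord,
    config: CodeConfig,
    index_date: dt.date = DEFAULT_INDEX_DATE,
    count_same_day: bool = False,
) -> dt.date | None:
    """Earliest qualification date under one clause, or None."""
    if clause.require_rx and patient.age_at(index_date) < RX_MIN_AGE:
        return None
    if clause.source is Source.PHYSICIAN:
        return _physician_clause_date(clause, patient, config, count_same_day)
    setting = Setting.INPATIENT if clause.source is Source.HOSPITAL else Setting.ER
    dates = hospital_ra_dates(patient, setting, config)
    entries = [(d, False) for d in dates]
    return window_satisfied(entries, clause.n_codes, clause.window_days)


# ---------------------------------------------------------------------------
# Exclusions


def exclusion_triggered(
    patient: PatientRecord,
    rule: ExclusionRule,
    qualification_date: dt.date | None = None,
    config: CodeConfig | None = None,
) -> bool:
    """Evaluate the enabled exclusion cases on the physician-claim stream.

    Case A: any OTHER_RHEUM-classified claim strictly after the patient's
    last RA-classified claim. Case B: any rheumatology-specialty claim with
    a non-RA code on/after the first RA claim (all rheumatology visits when
    the patient has no RA physician claims).
    """
    if not rule:
        return False
    if config is None:
        raise ValueError("config is required when exclusions are enabled")
    ra_dates = [
        c.service_date
        for c in patient.claims
        if classify_code(c.dx, config) is CodeClass.RA
    ]
    first_ra = min(ra_dates) if ra_dates else None
    last_ra = max(ra_dates) if ra_dates else None

    if rule.case_a and last_ra is not None:
        for c in patient.claims:
            if (
                c.service_date > last_ra
                and classify_code(c.dx, config) is CodeClass.OTHER_RHEUM
            ):
                return True
    if rule.case_b:
        anchor = first_ra if first_ra is not None else patient.obs_start
        for c in patient.claims:
            if (
                c.specialty.strip().lower() == "rheumatology"
                and c.service_date >= anchor
                and classify_code(c.dx, config) is not CodeClass.RA
            ):
                return True
    return False


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_algorithm(
    spec: AlgorithmSpec,
    patient: PatientRecord,
    config: CodeConfig,
    min_age: int | None = None,
    index_date: dt.date = DEFAULT_INDEX_DATE,
    count_same_day: bool = False,
) -> bool:
    """Classify one patient: positive iff any clause is satisfied and no
    enabled exclusion triggers. Deterministic and order-insensitive."""
    if min_age is not None and patient.age_at(index_date) < min_age:
        return False
    qualification: dt.date | None = None
    for clause in spec.clauses:
        date = clause_satisfied(clause, patient, config, index_date, count_same_day)
        if date is not None and (qualification is None or date < qualification):
            qualification = date
    if qualification is None:
        return False
    if spec.exclusions and exclusion_triggered(
        patient, spec.exclusions, qualification, config
    ):
        return False
    return True


# ---------------------------------------------------------------------------
# Mini-DSL


_CLAUSE_RE = re.compile(
    r"^(?P<n>\d+)(?P<src>[PHE])"
    r"(?:\((?P<mods>[^)]*)\))?"
    r"(?:/(?P<w>\d+)(?P<wu>[yd]))?$"
)
_EXCL_RE = re.compile(r"\s*excl\(\s*(?P<flags>[AB](?:\s*,\s*[AB])?)\s*\)\s*$")
_GAP_RE = re.compile(r"^gap>=(\d+)d$")

_SOURCES = {"P": Source.PHYSICIAN, "H": Source.HOSPITAL, "E": Source.ER}
_SOURCE_LETTER = {v: k for k, v in _SOURCES.items()}


def parse_algorithm_spec(text: str, algorithm_id: str | None = None) -> AlgorithmSpec:
    """Parse the algorithm grammar (see module docstring) into an
    :class:`AlgorithmSpec`. ``algorithm_id`` defaults to the canonical
    rendering of the parsed spec."""
    work = text
    exclusions = ExclusionRule()
    m = _EXCL_RE.search(work)
    if m:
        flags = {f.strip() for f in m.group("flags").split(",")}
        exclusions = ExclusionRule(case_a="A" in flags, case_b="B" in flags)
        work = work[: m.start()]

    clauses: list[Clause] = []
    offset = 0
    for part in work.split("|"):
        token = part.strip()
        if not token:
            raise DslError("empty clause", text.find(part, offset))
        cm = _CLAUSE_RE.match(token)
        if cm is None:
            raise DslError(f"cannot parse clause {token!r}", text.find(token, offset))
        n = int(cm.group("n"))
        if n == 0:
            raise DslError("clause count must be >= 1", text.find(token, offset))
        source = _SOURCES[cm.group("src")]
        gap = 0
        spec_req = False
        rx_req = False
        if cm.group("mods"):
            for mod in cm.group("mods").split(","):
                mod = mod.strip()
                if mod == "spec>=1":
                    spec_req = True
                elif mod == "rx>=1":
                    rx_req = True
                else:
                    gm = _GAP_RE.match(mod)
                    if gm is None:
                        raise DslError(
                            f"unknown modifier {mod!r}", text.find(token, offset)
                        )
                    gap = int(gm.group(1))
        window: int | None = EVER
        if cm.group("w"):
            window = int(cm.group("w")) * (365 if cm.group("wu") == "y" else 1)
            if window == 0:
                raise DslError("window must be positive", text.find(token, offset))
        try:
            clauses.append(
                Clause(
                    source=source,
                    n_codes=n,
                    window_days=window,
                    min_gap_days=gap,
                    require_specialist=spec_req,
                    require_rx=rx_req,
                )
            )
        except ValueError as exc:
            raise DslError(str(exc), text.find(token, offset)) from exc
        offset = text.find(part, offset) + len(part)

    spec = AlgorithmSpec(
        algorithm_id="", clauses=tuple(clauses), exclusions=exclusions
    )
    canonical = render_algorithm_spec(spec)
    return AlgorithmSpec(
        algorithm_id=algorithm_id or canonical,
        clauses=spec.clauses,
        exclusions=spec.exclusions,
    )


def _render_clause(c: Clause) -> str:
    mods = []
    if c.min_gap_days:
        mods.append(f"gap>={c.min_gap_days}d")
    if c.require_specialist:
        mods.append("spec>=1")
    if c.require_rx:
        mods.append("rx>=1")
    out = f"{c.n_codes}{_SOURCE_LETTER[c.source]}"
    if mods:
        out += "(" + ",".join(mods) + ")"
    if c.window_days is not EVER:
        if c.window_days % 365 == 0:
            out += f"/{c.window_days // 365}y"
        else:
            out += f"/{c.window_days}d"
    return out


def render_algorithm_spec(spec: AlgorithmSpec) -> str:
    """Canonical text form; ``parse(render(s))`` reproduces ``s``'s clauses."""
    out = " | ".join(_render_clause(c) for c in spec.clauses)
    if spec.exclusions:
        flags = [f for f, on in (("A", spec.exclusions.case_a), ("B", spec.exclusions.case_b)) if on]
        out += f" excl({','.join(flags)})"
    return out
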
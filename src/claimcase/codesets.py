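"""Diagnosis-code and specialty classification against configurable code sets.

Matching is by code prefix within a coding system, case-insensitive and
dot-insensitive ("M05.9" matches prefix "M05"). The RA prefix sets are fixed
by the case definitions under study; the "other rheumatology" sets are
implementer-supplied defaults (the conditions are named by the definitions
but no official code list accompanies them) and are fully overridable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .model import CodeSystem, DiagnosisCode, DrugClass

__all__ = [
    "CodeClass",
    "CodeConfig",
    "classify_code",
    "is_msk_specialist",
    "load_code_config",
    "default_code_config",
]


class CodeClass(str, enum.Enum):
    RA = "RA"
    OTHER_RHEUM = "OTHER_RHEUM"
    OTHER = "OTHER"


def _norm(code: str) -> str:
    """Normalise a code or prefix: uppercase, dots stripped."""
    return code.replace(".", "").strip().upper()


_DEFAULT_RA = {
    CodeSystem.OHIP_DX: ("714",),
    CodeSystem.ICD9: ("714",),
    CodeSystem.ICD10: ("M05", "M06"),
}

# Implementer defaults: osteoarthritis, gout, polymyalgia rheumatica,
# spondyloarthropathy / ankylosing spondylitis, connective tissue disorder,
# psoriasis, synovitis/tenosynovitis/bursitis, vasculitis.
_DEFAULT_OTHER_RHEUM = {
    CodeSystem.OHIP_DX: ("715", "274", "725", "720", "710", "696", "727", "446", "447"),
    CodeSystem.ICD9: ("715", "274", "725", "720", "710", "696", "727", "446", "447"),
    CodeSystem.ICD10: (
        "M15", "M16", "M17", "M18", "M19",  # osteoarthritis
        "M10",                              # gout
        "M353",                             # polymyalgia rheumatica
        "M45", "M46",                       # ankylosing spondylitis / spondylopathies
        "M30", "M31", "M32", "M33", "M34", "M35",  # connective tissue / vasculitis
        "L40",                              # psoriasis
        "M65", "M70", "M71",                # synovitis / tenosynovitis / bursitis
    ),
}

_DEFAULT_MSK = frozenset({"rheumatology", "orthopedic surgery", "internal medicine"})

_DEFAULT_DRUG_MAP = {
    "methotrexate": DrugClass.DMARD,
    "hydroxychloroquine": DrugClass.DMARD,
    "sulfasalazine": DrugClass.DMARD,
    "leflunomide": DrugClass.DMARD,
    "etanercept": DrugClass.BIOLOGIC,
    "infliximab": DrugClass.BIOLOGIC,
    "adalimumab": DrugClass.BIOLOGIC,
    "prednisone": DrugClass.GLUCOCORTICOSTEROID,
    "methylprednisolone": DrugClass.GLUCOCORTICOSTEROID,
    "naproxen": DrugClass.NSAID_COXIB,
    "celecoxib": DrugClass.NSAID_COXIB,
    "ibuprofen": DrugClass.NSAID_COXIB,
}


@dataclass(frozen=True)
class CodeConfig:
    """Prefix sets and specialty/drug maps driving event classification."""

    ra_prefixes: Mapping[CodeSystem, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_RA)
    )
    other_rheum_prefixes: Mapping[CodeSystem, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_OTHER_RHEUM)
    )
    msk_specialties: frozenset[str] = _DEFAULT_MSK
    drug_class_map: Mapping[str, DrugClass] = field(
        default_factory=lambda: dict(_DEFAULT_DRUG_MAP)
    )

    def __post_init__(self) -> None:
        for system, prefixes in self.ra_prefixes.items():
            if not prefixes:
                raise ValueError(f"empty RA prefix list for {system}")
            others = {_norm(p) for p in self.other_rheum_prefixes.get(system, ())}
            for p in prefixes:
                np = _norm(p)
                for q in others:
                    if np.startswith(q) or q.startswith(np):
                        raise ValueError(
                            f"RA prefix {p!r} overlaps other-rheum prefix {q!r} "
                            f"in {system}"
                        )

    def classify_drug(self, identifier: str) -> DrugClass:
        return self.drug_class_map.get(identifier.strip().lower(), DrugClass.OTHER)


def classify_code(code: DiagnosisCode, config: CodeConfig) -> CodeClass:
    """Classify one diagnosis code as RA, OTHER_RHEUM or OTHER.

    Raises ``KeyError`` if the code's system is not configured — a code from
    an unknown system is never silently OTHER.
    """
    if code.system not in config.ra_prefixes:
        raise KeyError(f"code system {code.system} not present in config")
    value = _norm(code.value)
    if any(value.startswith(_norm(p)) for p in config.ra_prefixes[code.system]):
        return CodeClass.RA
    if any(
        value.startswith(_norm(p))
        for p in config.other_rheum_prefixes.get(code.system, ())
    ):
        return CodeClass.OTHER_RHEUM
    return CodeClass.OTHER


def is_msk_specialist(specialty: str, config: CodeConfig) -> bool:
    """True iff the (normalised) specialty is a musculoskeletal specialty."""
    return specialty.strip().lower() in config.msk_specialties


def load_code_config(path: str | Path) -> CodeConfig:
    """Load a CodeConfig from YAML (keys as in the shipped default file)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    ra = {CodeSystem(k): tuple(v) for k, v in raw["ra_prefixes"].items()}
    other = {
        CodeSystem(k): tuple(v) for k, v in raw.get("other_rheum_prefixes", {}).items()
    }
    msk = frozenset(s.strip().lower() for s in raw.get("msk_specialties", []))
    drugs = {
        k.strip().lower(): DrugClass(v) for k, v in raw.get("drug_class_map", {}).items()
    }
    return CodeConfig(
        ra_prefixes=ra,
        other_rheum_prefixes=other,
        msk_specialties=msk or _DEFAULT_MSK,
        drug_class_map=drugs or dict(_DEFAULT_DRUG_MAP),
    )


def default_code_config() -> CodeConfig:
    return CodeConfig()
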
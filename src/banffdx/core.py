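"""Core domain types for Banff-based kidney-allograft rejection classification.

The Banff schema scores individual biopsy lesions on an ordinal 0-3 scale
(tubulitis ``t``, interstitial inflammation ``i``, intimal arteritis ``v``,
glomerulitis ``g``, peritubular capillaritis ``ptc``, C4d staining, and the
chronic lesions ``cg``, ``cv``, ``ci``, ``ct``, ``ptcbm``, plus the
IFTA-region scores ``t-IFTA`` and ``i-IFTA``).  A rule engine maps one such
score vector, together with a minimal clinical context (donor-specific
antibody status, ABO compatibility), to a closed set of diagnostic
categories.  This module holds those types, the controlled vocabularies,
and record validation; the decision rules themselves live in
:mod:`banffdx.amr`, :mod:`banffdx.tcmr` and :mod:`banffdx.pipeline`.

A lesion score is either an integer in ``{0, 1, 2, 3}`` or *missing*
(``None``).  Missing is semantically distinct from 0: a pathology report
that does not score a lesion ("–" in printed tables) is not asserting its
absence.  The rule engine treats missing as 0 where a threshold is tested,
but I/O preserves the distinction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "LESION_FIELDS",
    "Abo",
    "BanffLesionScores",
    "BiopsyRecord",
    "BiopsyType",
    "ClinicalContext",
    "DiagnosisCategory",
    "DiagnosisResult",
    "Dsa",
    "IftaGrade",
    "RejectionLevel",
    "TcmrGrade",
    "ValidationFinding",
    "rejection_level",
    "validate_record",
]

#: Ordinal lesion-score fields, in canonical column order.
LESION_FIELDS: tuple[str, ...] = (
    "t", "t_ifta", "i", "i_ifta", "v", "g", "ptc",
    "c4d", "cg", "cv", "ci", "ct", "ptcbm",
)


class Dsa(enum.Enum):
    """Donor-specific anti-HLA antibody serology."""

    POSITIVE = "+"
    NEGATIVE = "-"
    UNKNOWN = "unknown"


class Abo(enum.Enum):
    """ABO blood-group compatibility of the transplant."""

    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"


class BiopsyType(enum.Enum):
    """Why the biopsy was taken (metadata only; never consulted by rules)."""

    PROTOCOL = "protocol"
    FOR_CAUSE = "for_cause"
    FOLLOW_UP = "follow_up"


class DiagnosisCategory(enum.Enum):
    """Closed vocabulary of engine output categories.

    The ten base categories; acute TCMR and IFTA additionally carry a
    grade on the :class:`DiagnosisResult`.
    """

    A_AMR = "A-AMR"
    CA_AMR = "CA-AMR"
    C_AMR_INACTIVE = "C-AMR-INACTIVE"
    EQUIVOCAL_AMR = "EQUIVOCAL-AMR"
    A_TCMR = "A-TCMR"
    CA_TCMR = "CA-TCMR"
    BC = "BC"
    IFTA = "IFTA"
    C4D_NO_REJECTION = "C4D-NO-REJECTION"
    NO_REJECTION = "NO-REJECTION"


class TcmrGrade(enum.Enum):
    IA = "IA"
    IB = "IB"
    IIA = "IIA"
    IIB = "IIB"
    III = "III"


class IftaGrade(enum.Enum):
    I = "I"
    II = "II"
    III = "III"


class RejectionLevel(enum.Enum):
    REJECTION = "rejection"
    NON_REJECTION = "non-rejection"


#: Categories that count as rejection when agreement is assessed at the
#: rejection / non-rejection level.  Borderline change and IFTA sit on the
#: non-rejection side, as does inactive chronic AMR.
REJECTION_CATEGORIES: frozenset[DiagnosisCategory] = frozenset(
    {
        DiagnosisCategory.A_AMR,
        DiagnosisCategory.CA_AMR,
        DiagnosisCategory.EQUIVOCAL_AMR,
        DiagnosisCategory.A_TCMR,
        DiagnosisCategory.CA_TCMR,
    }
)


def rejection_level(category: DiagnosisCategory) -> RejectionLevel:
    """Map a base category to the rejection / non-rejection dichotomy."""
    if not isinstance(category, DiagnosisCategory):
        raise ValueError(f"unknown diagnosis category: {category!r}")
    if category in REJECTION_CATEGORIES:
        return RejectionLevel.REJECTION
    return RejectionLevel.NON_REJECTION


Score = Optional[int]  # ordinal 0-3, or None for missing


@dataclass(frozen=True)
class BanffLesionScores:
    """One biopsy's ordinal lesion-score vector.

    Each field is an integer in ``[0, 3]`` or ``None`` (missing).
    """

    t: Score = None
    t_ifta: Score = None
    i: Score = None
    i_ifta: Score = None
    v: Score = None
    g: Score = None
    ptc: Score = None
    c4d: Score = None
    cg: Score = None
    cv: Score = None
    ci: Score = None
    ct: Score = None
    ptcbm: Score = None

    def value(self, name: str) -> int:
        """Score for *name* with missing coerced to 0 (rule-engine view)."""
        v = getattr(self, name)
        return 0 if v is None else v

    def as_dict(self) -> dict[str, Score]:
        return {f: getattr(self, f) for f in LESION_FIELDS}


@dataclass(frozen=True)
class ClinicalContext:
    """Clinical flags consulted by (or carried alongside) the rule engine.

    Only ``dsa``, ``abo`` and ``tma_present`` are engine inputs, and TMA
    fires no rule — it is carried into reports only.  Biopsy type and
    post-transplant day are metadata.
    """

    dsa: Dsa
    abo: Abo
    tma_present: bool = False
    biopsy_type: Optional[BiopsyType] = None
    day_after_tx: Optional[int] = None


@dataclass(frozen=True)
class BiopsyRecord:
    """One biopsy: scores, context, and optional reference labels.

    ``pathologist_dx`` holds the pathologist's diagnosis verbatim (free
    text allowed: recurrent glomerulonephritis, BKV nephropathy, ... appear
    only as pathologist labels, never as engine outputs).
    ``expected_engine_dx`` and ``known_deviation`` are fixture-only fields
    used for regression against published reference classifications.
    """

    record_id: str
    patient_id: str
    scores: BanffLesionScores
    context: ClinicalContext
    bx_year: Optional[int] = None
    pathologist_dx: Optional[str] = None
    expected_engine_dx: Optional[DiagnosisCategory] = None
    known_deviation: bool = False

    def __post_init__(self) -> None:
        if self.known_deviation and self.expected_engine_dx is None:
            raise ValueError(
                f"{self.record_id}: known_deviation requires expected_engine_dx"
            )

    def with_pathologist_dx(self, dx: str) -> "BiopsyRecord":
        return replace(self, pathologist_dx=dx)


@dataclass(frozen=True)
class ValidationFinding:
    """One validation problem: the field, the offending value, the rule."""

    record_id: str
    field_name: str
    value: object
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.record_id}.{self.field_name}={self.value!r}: {self.message}"


def validate_record(record: BiopsyRecord) -> list[ValidationFinding]:
    """Check a record against the schema invariants.

    Returns an empty list iff every present lesion score is an integer in
    ``[0, 3]`` and the required context fields are set.  Missing scores are
    legal.  The record is never mutated.
    """
    findings: list[ValidationFinding] = []
    for name in LESION_FIELDS:
        v = getattr(record.scores, name)
        if v is None:
            continue
        if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 3:
            findings.append(
                ValidationFinding(
                    record.record_id, name, v,
                    "lesion score must be an integer in [0, 3] or missing",
                )
            )
    if not isinstance(record.context.dsa, Dsa):
        findings.append(
            ValidationFinding(
                record.record_id, "dsa", record.context.dsa,
                "DSA status must be set (unknown is a legal value)",
            )
        )
    if not isinstance(record.context.abo, Abo):
        findings.append(
            ValidationFinding(
                record.record_id, "abo", record.context.abo,
                "ABO compatibility must be set",
            )
        )
    day = record.context.day_after_tx
    if day is not None and (not isinstance(day, int) or day < 0):
        findings.append(
            ValidationFinding(
                record.record_id, "day_after_tx", day,
                "day after transplant must be a non-negative integer",
            )
        )
    return findings


@dataclass(frozen=True)
class DiagnosisResult:
    """Engine output for one biopsy.

    ``applicable`` is the full set of categories whose criteria hold;
    ``primary`` is the single category selected by the fixed priority
    order; ``trace`` lists the fired rule identifiers in order.
    """

    applicable: frozenset[DiagnosisCategory]
    primary: DiagnosisCategory
    trace: tuple[str, ...]
    tcmr_grade: Optional[TcmrGrade] = None
    ifta_grade: Optional[IftaGrade] = None

    def __post_init__(self) -> None:
        if self.primary not in self.applicable | {DiagnosisCategory.NO_REJECTION}:
            raise ValueError("primary must be applicable or NO_REJECTION")
        if not self.trace:
            raise ValueError("trace must be non-empty")
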
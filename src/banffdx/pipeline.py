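"""Assemble per-biopsy findings into a single primary diagnosis.

The AMR and TCMR engines each yield zero or more applicable categories;
IFTA (graded from the worse of ci and ct) and "C4d staining without
evidence of rejection" complete the set.  The primary category is the
highest-ranked applicable one under a fixed clinical priority, with
equivocal-for-AMR sharing the A-AMR slot; an empty set means no evidence
of rejection.
"""

from __future__ import annotations

from typing import Iterable, Optional

from . import amr as _amr
from . import tcmr as _tcmr
from .core import (
    Abo,
    BanffLesionScores,
    BiopsyRecord,
    ClinicalContext,
    DiagnosisCategory,
    DiagnosisResult,
    IftaGrade,
    REJECTION_CATEGORIES,
    validate_record,
)

__all__ = [
    "PRIORITY",
    "ValidationError",
    "applicable_categories",
    "c4d_without_rejection",
    "classify_biopsy",
    "ifta_grade",
    "select_primary",
]

#: Fixed priority for primary-category selection (highest first).
#: Equivocal-for-AMR is folded into the A-AMR slot.
PRIORITY: tuple[DiagnosisCategory, ...] = (
    DiagnosisCategory.A_AMR,
    DiagnosisCategory.CA_AMR,
    DiagnosisCategory.A_TCMR,
    DiagnosisCategory.CA_TCMR,
    DiagnosisCategory.C_AMR_INACTIVE,
    DiagnosisCategory.BC,
    DiagnosisCategory.IFTA,
    DiagnosisCategory.C4D_NO_REJECTION,
    DiagnosisCategory.NO_REJECTION,
)

_PRIORITY_RANK: dict[DiagnosisCategory, int] = {
    **{c: i for i, c in enumerate(PRIORITY)},
    DiagnosisCategory.EQUIVOCAL_AMR: PRIORITY.index(DiagnosisCategory.A_AMR),
}


class ValidationError(ValueError):
    """Raised when a record fails validation; carries the findings."""

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__("; ".join(str(f) for f in self.findings))


def ifta_grade(scores: BanffLesionScores) -> Optional[IftaGrade]:
    """IFTA grade from the worse of ci and ct (missing as 0); None if both 0."""
    m = max(scores.value("ci"), scores.value("ct"))
    if m == 0:
        return None
    return (IftaGrade.I, IftaGrade.II, IftaGrade.III)[m - 1]


def c4d_without_rejection(
    scores: BanffLesionScores,
    context: ClinicalContext,
    applicable: frozenset[DiagnosisCategory] | set[DiagnosisCategory],
) -> bool:
    """Positive C4d with no other histologic finding, ABO-compatible only.

    In ABO-incompatible grafts C4d positivity is expected and the category
    is suppressed (the biopsy reads as no rejection).
    """
    if scores.value("c4d") < _amr.C4D_POSITIVE_THRESHOLD:
        return False
    if context.abo is not Abo.COMPATIBLE:
        return False
    blocked = REJECTION_CATEGORIES | {DiagnosisCategory.IFTA}
    return not (set(applicable) & blocked)


def applicable_categories(
    scores: BanffLesionScores, context: ClinicalContext
) -> frozenset[DiagnosisCategory]:
    """All categories whose criteria hold for this biopsy (may be empty)."""
    result, _ = _evaluate(scores, context)
    return result


def _evaluate(
    scores: BanffLesionScores, context: ClinicalContext
) -> tuple[frozenset[DiagnosisCategory], dict]:
    amr_a = _amr.classify_amr(scores, context)
    tcmr_a = _tcmr.classify_tcmr(scores)
    ifta = ifta_grade(scores)

    applicable: set[DiagnosisCategory] = set()
    if amr_a.category is not None:
        applicable.add(amr_a.category)
    if tcmr_a.acute_grade is not None:
        applicable.add(DiagnosisCategory.A_TCMR)
    if tcmr_a.chronic_active:
        applicable.add(DiagnosisCategory.CA_TCMR)
    if tcmr_a.borderline:
        applicable.add(DiagnosisCategory.BC)
    if ifta is not None:
        applicable.add(DiagnosisCategory.IFTA)
    if c4d_without_rejection(scores, context, applicable):
        applicable.add(DiagnosisCategory.C4D_NO_REJECTION)

    parts = {"amr": amr_a, "tcmr": tcmr_a, "ifta": ifta}
    return frozenset(applicable), parts


def select_primary(
    applicable: Iterable[DiagnosisCategory],
) -> DiagnosisCategory:
    """Highest-priority applicable category; NO_REJECTION when empty."""
    cats = list(applicable)
    for c in cats:
        if c not in _PRIORITY_RANK:
            raise ValueError(f"category outside the vocabulary: {c!r}")
    if not cats:
        return DiagnosisCategory.NO_REJECTION
    return min(cats, key=_PRIORITY_RANK.__getitem__)


def classify_biopsy(record: BiopsyRecord) -> DiagnosisResult:
    """Classify one validated biopsy record; pure and deterministic."""
    findings = validate_record(record)
    if findings:
        raise ValidationError(findings)

    applicable, parts = _evaluate(record.scores, record.context)
    primary = select_primary(applicable)

    trace = list(parts["amr"].trace) + list(parts["tcmr"].trace)
    if parts["ifta"] is not None:
        trace.append(f"ifta.grade={parts['ifta'].value}")
    if DiagnosisCategory.C4D_NO_REJECTION in applicable:
        trace.append("c4d_without_rejection")
    trace.append(f"primary={primary.value}")

    return DiagnosisResult(
        applicable=applicable,
        primary=primary,
        trace=tuple(trace),
        tcmr_grade=parts["tcmr"].acute_grade,
        ifta_grade=parts["ifta"],
    )
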
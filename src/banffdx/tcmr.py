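"""T-cell-mediated rejection (TCMR) rules.

Acute TCMR is graded from intimal arteritis (v) and the
tubulitis/inflammation pair (t, i); vascular grades take precedence.
Borderline change (BC) covers tubulointerstitial inflammation below the
diagnostic threshold.  Chronic active TCMR requires inflammation in
fibrotic cortex (i-IFTA >= 2) together with diagnostic tubulitis either in
preserved cortex (t >= 2) or within IFTA regions backed by established
tubular atrophy (t-IFTA >= 2 with ct >= 2).  Missing scores count as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import BanffLesionScores, DiagnosisCategory, TcmrGrade

__all__ = [
    "TcmrAssessment",
    "acute_tcmr_grade",
    "ca_tcmr_present",
    "classify_tcmr",
    "is_borderline",
]


@dataclass(frozen=True)
class TcmrAssessment:
    """Intermediate TCMR evaluation for one biopsy.

    ``category`` is the TCMR engine's own precedence (acute grade, then
    chronic active, then borderline); when both an acute grade and the
    chronic-active criteria hold, downstream assembly reports both in the
    applicable set.
    """

    borderline: bool
    acute_grade: Optional[TcmrGrade]
    chronic_active: bool
    category: Optional[DiagnosisCategory]
    trace: tuple[str, ...]


def acute_tcmr_grade(scores: BanffLesionScores) -> Optional[TcmrGrade]:
    """Acute TCMR grade, or None below threshold.

    Vascular lesions grade II-III regardless of tubulointerstitial scores
    (v=1 -> IIA, v=2 -> IIB, v=3 -> III); otherwise i >= 2 with t=3 -> IB,
    i >= 2 with t=2 -> IA.
    """
    v = scores.value("v")
    if v == 3:
        return TcmrGrade.III
    if v == 2:
        return TcmrGrade.IIB
    if v == 1:
        return TcmrGrade.IIA
    if scores.value("i") >= 2:
        if scores.value("t") == 3:
            return TcmrGrade.IB
        if scores.value("t") == 2:
            return TcmrGrade.IA
    return None


def is_borderline(scores: BanffLesionScores) -> bool:
    """Borderline change: tubulointerstitial inflammation below grade I.

    No arteritis, no acute grade, and either any tubulitis with minimal
    interstitial inflammation (t >= 1, i <= 1) or significant inflammation
    with minimal tubulitis (i >= 2, t = 1).
    """
    if scores.value("v") != 0 or acute_tcmr_grade(scores) is not None:
        return False
    t = scores.value("t")
    i = scores.value("i")
    return (t >= 1 and i <= 1) or (i >= 2 and t == 1)


def ca_tcmr_present(scores: BanffLesionScores) -> bool:
    """Chronic active TCMR criteria.

    i-IFTA >= 2 together with tubulitis t >= 2 in preserved cortex, or
    tubulitis within IFTA regions (t-IFTA >= 2) backed by tubular atrophy
    ct >= 2.  ci does not veto.
    """
    if scores.value("i_ifta") < 2:
        return False
    if scores.value("t") >= 2:
        return True
    return scores.value("t_ifta") >= 2 and scores.value("ct") >= 2


def classify_tcmr(scores: BanffLesionScores) -> TcmrAssessment:
    """Evaluate the TCMR rules for one biopsy."""
    grade = acute_tcmr_grade(scores)
    chronic = ca_tcmr_present(scores)
    borderline = is_borderline(scores)

    trace: list[str] = []
    category: Optional[DiagnosisCategory] = None
    if grade is not None:
        category = DiagnosisCategory.A_TCMR
        trace.append(f"tcmr.acute_grade={grade.value}")
    if chronic:
        if category is None:
            category = DiagnosisCategory.CA_TCMR
        trace.append("tcmr.chronic_active")
    if borderline:
        if category is None:
            category = DiagnosisCategory.BC
        trace.append("tcmr.borderline")
    if category is None:
        trace.append("tcmr.none")

    return TcmrAssessment(
        borderline=borderline,
        acute_grade=grade,
        chronic_active=chronic,
        category=category,
        trace=tuple(trace),
    )
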
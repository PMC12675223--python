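"""Antibody-mediated rejection (AMR) rules.

Active / chronic-active AMR is decided from the classic triad: histologic
microvascular inflammation (criterion 1), evidence of antibody-endothelium
interaction (criterion 2), and chronicity (transplant glomerulopathy).
Two context-sensitive refinements matter in a cohort rich in
ABO-incompatible grafts:

* C4d deposition in peritubular capillaries is near-universal in
  ABO-incompatible grafts without rejection, so a positive C4d stain
  (score >= 2) counts as evidence of antibody interaction only in
  ABO-compatible grafts.
* Isolated peritubular capillaritis (ptc >= 1 with g = 0) is a weak
  histologic signal.  It does not satisfy criterion 1 when it is better
  explained by concurrent full TCMR (unless C4d evidence plus MVI >= 2
  independently anchor an antibody process), nor in an ABO-incompatible
  graft without donor-specific antibody.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from .core import Abo, BanffLesionScores, ClinicalContext, DiagnosisCategory, Dsa
from . import tcmr as _tcmr

__all__ = [
    "AmrAssessment",
    "TcmrFlags",
    "c4d_evidence",
    "chronicity",
    "classify_amr",
    "concurrent_tcmr_flags",
    "criterion1_histologic",
    "criterion2_interaction",
    "mvi_score",
]

C4D_POSITIVE_THRESHOLD = 2  # immunofluorescence convention
MVI_THRESHOLD = 2


class TcmrFlags(NamedTuple):
    """Concurrent T-cell findings that modulate the ptc-only AMR path."""

    full_tcmr: bool
    borderline: bool


@dataclass(frozen=True)
class AmrAssessment:
    """Intermediate AMR evaluation for one biopsy."""

    mvi: int
    c4d_evidence: bool
    criterion1_histologic: bool
    criterion2_interaction: bool
    chronic: bool
    category: Optional[DiagnosisCategory]
    trace: tuple[str, ...]


def mvi_score(scores: BanffLesionScores) -> int:
    """Microvascular inflammation score, g + ptc (missing counts as 0)."""
    return scores.value("g") + scores.value("ptc")


def c4d_evidence(c4d: Optional[int], context: ClinicalContext) -> bool:
    """Whether C4d staining counts as evidence of antibody interaction.

    True iff c4d >= 2 in an ABO-*compatible* graft.  In ABO-incompatible
    grafts C4d positivity is expected regardless of rejection and never
    counts.  Missing C4d is treated as negative.
    """
    if c4d is None:
        return False
    return c4d >= C4D_POSITIVE_THRESHOLD and context.abo is Abo.COMPATIBLE


def concurrent_tcmr_flags(scores: BanffLesionScores) -> TcmrFlags:
    """Concurrent T-cell-mediated findings, per the TCMR engine definitions.

    ``full_tcmr`` means a diagnostic TCMR is present (acute grade or
    chronic-active criteria); ``borderline`` means borderline changes only.
    """
    full = (
        _tcmr.acute_tcmr_grade(scores) is not None
        or _tcmr.ca_tcmr_present(scores)
    )
    borderline = (not full) and _tcmr.is_borderline(scores)
    return TcmrFlags(full_tcmr=full, borderline=borderline)


def criterion1_histologic(
    scores: BanffLesionScores, context: ClinicalContext, flags: TcmrFlags
) -> bool:
    """Histologic evidence of microvascular injury (AMR criterion 1).

    Glomerulitis (g >= 1) always qualifies.  Isolated peritubular
    capillaritis (ptc >= 1, g = 0) qualifies unless either ptc-only block
    applies:

    a. concurrent full TCMR explains the capillaritis, unless C4d evidence
       AND MVI >= 2 both hold (borderline changes alone do not block);
    b. ABO-incompatible graft without positive DSA.
    """
    g = scores.value("g")
    ptc = scores.value("ptc")
    if g >= 1:
        return True
    if ptc < 1:
        return False
    # ptc-only path
    strong_antibody_signal = (
        c4d_evidence(scores.c4d, context) and mvi_score(scores) >= MVI_THRESHOLD
    )
    if flags.full_tcmr and not strong_antibody_signal:
        return False
    if context.abo is Abo.INCOMPATIBLE and context.dsa is not Dsa.POSITIVE:
        return False
    return True


def criterion2_interaction(
    scores: BanffLesionScores, context: ClinicalContext
) -> bool:
    """Evidence of antibody-endothelium interaction (AMR criterion 2).

    C4d evidence (ABO-compatible positivity) or moderate microvascular
    inflammation (MVI >= 2).  DSA positivity alone is not required: under
    the implemented revision, MVI-positive / DSA-negative / C4d-negative
    biopsies still qualify.
    """
    return c4d_evidence(scores.c4d, context) or mvi_score(scores) >= MVI_THRESHOLD


def chronicity(scores: BanffLesionScores) -> bool:
    """Chronic glomerular injury: transplant glomerulopathy cg >= 1.

    PTC basement-membrane multilayering (ptcbm) alone is insufficient.
    """
    return scores.value("cg") >= 1


def classify_amr(
    scores: BanffLesionScores, context: ClinicalContext
) -> AmrAssessment:
    """Evaluate the AMR rules for one biopsy.

    ``category`` is ``None`` unless criteria 1 and 2 both hold; otherwise
    CA-AMR when chronic, equivocal when DSA is unknown without C4d
    evidence, else A-AMR.
    """
    flags = concurrent_tcmr_flags(scores)
    mvi = mvi_score(scores)
    c4d_ev = c4d_evidence(scores.c4d, context)
    c1 = criterion1_histologic(scores, context, flags)
    c2 = criterion2_interaction(scores, context)
    chronic = chronicity(scores)

    trace: list[str] = []
    trace.append(f"amr.mvi={mvi}")
    trace.append(f"amr.c4d_evidence={'yes' if c4d_ev else 'no'}")
    trace.append(f"amr.criterion1={'yes' if c1 else 'no'}")
    trace.append(f"amr.criterion2={'yes' if c2 else 'no'}")

    category: Optional[DiagnosisCategory] = None
    if c1 and c2:
        if chronic:
            category = DiagnosisCategory.CA_AMR
            trace.append("amr.chronic_active:cg>=1")
        elif context.dsa is Dsa.UNKNOWN and not c4d_ev:
            category = DiagnosisCategory.EQUIVOCAL_AMR
            trace.append("amr.equivocal:dsa_unknown_without_c4d")
        else:
            category = DiagnosisCategory.A_AMR
            trace.append("amr.active")

    return AmrAssessment(
        mvi=mvi,
        c4d_evidence=c4d_ev,
        criterion1_histologic=c1,
        criterion2_interaction=c2,
        chronic=chronic,
        category=category,
        trace=tuple(trace),
    )
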
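"""Pathologist-vs-engine agreement analysis.

Builds the pathologist x engine contingency ("flow") table that underlies
a Sankey diagram, computes stratified agreement rates (overall,
non-rejection, rejection, exact rejection type) and Cohen's kappa, and
extracts row-level discrepancy listings analogous to published
discrepancy tables.

Pathologist labels may be free text; non-rejection disease entities
(recurrent glomerulonephritis, BKV nephropathy, TMA, ...) collapse into a
single OTHER bucket on the non-rejection side.  Cohen's kappa is an
extension beyond the agreement rates — a standard chance-corrected
statistic reported alongside them and labelled as such.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    BiopsyRecord,
    DiagnosisCategory,
    REJECTION_CATEGORIES,
    RejectionLevel,
)
from .io import normalize_diagnosis_label
from .pipeline import classify_biopsy

__all__ = [
    "AgreementRate",
    "AgreementReport",
    "DiscrepancyPanels",
    "FlowTable",
    "OTHER",
    "Stratum",
    "agreement_rate",
    "agreement_report",
    "build_flow_table",
    "cohen_kappa",
    "discrepancy_panels",
    "discrepancy_records",
]

#: Bucket for pathologist labels outside the engine vocabulary.
OTHER = "OTHER"

_AMR_FAMILY = {
    DiagnosisCategory.A_AMR,
    DiagnosisCategory.CA_AMR,
    DiagnosisCategory.EQUIVOCAL_AMR,
}
_TCMR_FAMILY = {DiagnosisCategory.A_TCMR, DiagnosisCategory.CA_TCMR}

Label = Union[DiagnosisCategory, str]


class Stratum(enum.Enum):
    OVERALL = "overall"
    NON_REJECTION = "non-rejection"
    REJECTION = "rejection"
    EXACT_TYPE = "exact-type"


def _label_key(label: Label) -> str:
    return label.value if isinstance(label, DiagnosisCategory) else str(label)


def _is_rejection(label: Label) -> bool:
    return isinstance(label, DiagnosisCategory) and label in REJECTION_CATEGORIES


@dataclass(frozen=True)
class FlowTable:
    """Pathologist x engine contingency table with marginals.

    ``rows``/``cols`` are label sequences (categories, or the OTHER
    bucket on the pathologist side); ``counts[i, j]`` is the number of
    biopsies labelled ``rows[i]`` by the pathologist and ``cols[j]`` by
    the engine.
    """

    rows: tuple[Label, ...]
    cols: tuple[Label, ...]
    counts: np.ndarray  # shape (len(rows), len(cols)), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def row_marginals(self) -> dict[str, int]:
        return {
            _label_key(r): int(s) for r, s in zip(self.rows, self.counts.sum(axis=1))
        }

    def col_marginals(self) -> dict[str, int]:
        return {
            _label_key(c): int(s) for c, s in zip(self.cols, self.counts.sum(axis=0))
        }

    def cell(self, row: Label, col: Label) -> int:
        return int(self.counts[self.rows.index(row), self.cols.index(col)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[_label_key(r) for r in self.rows],
            columns=[_label_key(c) for c in self.cols],
        )

    def to_long_csv(self, path: Union[str, Path]) -> None:
        """Export as long-format CSV: pathologist,engine,count."""
        frame = self.to_frame()
        long = (
            frame.rename_axis("pathologist")
            .reset_index()
            .melt(id_vars="pathologist", var_name="engine", value_name="count")
        )
        long = long[long["count"] > 0]
        long.to_csv(path, index=False)

    def to_sankey_json(self, path: Optional[Union[str, Path]] = None) -> dict:
        """Node/link structure suitable for Sankey rendering."""
        nodes = [
            *({"name": _label_key(r), "side": "pathologist"} for r in self.rows),
            *({"name": _label_key(c), "side": "engine"} for c in self.cols),
        ]
        links = []
        for i, r in enumerate(self.rows):
            for j, c in enumerate(self.cols):
                n = int(self.counts[i, j])
                if n:
                    links.append(
                        {"source": i, "target": len(self.rows) + j, "value": n}
                    )
        payload = {"nodes": nodes, "links": links, "n_total": self.n_total}
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def _pathologist_label(record: BiopsyRecord) -> Label:
    if record.pathologist_dx is None:
        raise ValueError(f"record {record.record_id} has no pathologist_dx")
    cat = normalize_diagnosis_label(record.pathologist_dx)
    return cat if cat is not None else OTHER


def _engine_labels(
    records: Sequence[BiopsyRecord],
    engine: Optional[Mapping[str, DiagnosisCategory]],
) -> list[DiagnosisCategory]:
    if engine is None:
        return [classify_biopsy(r).primary for r in records]
    out = []
    for r in records:
        if r.record_id not in engine:
            raise ValueError(f"record {r.record_id} has no engine result")
        out.append(engine[r.record_id])
    return out


def build_flow_table(
    records: Sequence[BiopsyRecord],
    engine: Optional[Mapping[str, DiagnosisCategory]] = None,
) -> FlowTable:
    """Cross-tabulate pathologist labels against engine primaries.

    ``engine`` maps record_id to the engine's primary category; when
    omitted the records are classified in place.
    """
    engine_labels = _engine_labels(records, engine)
    path_labels = [_pathologist_label(r) for r in records]

    row_order: list[Label] = [
        c for c in DiagnosisCategory if c in set(path_labels)
    ]
    if OTHER in path_labels:
        row_order.append(OTHER)
    col_order: list[Label] = [c for c in DiagnosisCategory if c in set(engine_labels)]

    counts = np.zeros((len(row_order), len(col_order)), dtype=int)
    for p, e in zip(path_labels, engine_labels):
        counts[row_order.index(p), col_order.index(e)] += 1
    return FlowTable(rows=tuple(row_order), cols=tuple(col_order), counts=counts)


@dataclass(frozen=True)
class AgreementRate:
    rate: float
    numerator: int
    denominator: int

    @property
    def percent(self) -> float:
        """Rate in percent, rounded to one decimal (presentation only)."""
        return round(100.0 * self.rate, 1)


def _base_match(row: Label, col: Label) -> bool:
    # exact base-category agreement; OTHER never matches an engine output
    return isinstance(row, DiagnosisCategory) and row is col


def agreement_rate(flow: FlowTable, stratum: Stratum) -> AgreementRate:
    """Agreement between pathologist and engine within a stratum.

    OVERALL: base-category agreement over all biopsies.  NON_REJECTION /
    REJECTION: among biopsies the pathologist placed on that side,
    the fraction the engine places on the same side (OTHER, BC and IFTA
    count as non-rejection).  EXACT_TYPE: among pathologist-rejection
    biopsies, the fraction with the identical rejection category.
    """
    num = 0
    den = 0
    for i, r in enumerate(flow.rows):
        for j, c in enumerate(flow.cols):
            n = int(flow.counts[i, j])
            if n == 0:
                continue
            if stratum is Stratum.OVERALL:
                den += n
                num += n * _base_match(r, c)
            elif stratum is Stratum.NON_REJECTION:
                if not _is_rejection(r):
                    den += n
                    num += n * (not _is_rejection(c))
            elif stratum is Stratum.REJECTION:
                if _is_rejection(r):
                    den += n
                    num += n * _is_rejection(c)
            elif stratum is Stratum.EXACT_TYPE:
                if _is_rejection(r):
                    den += n
                    num += n * _base_match(r, c)
    if den == 0:
        raise ValueError(f"agreement rate undefined: empty {stratum.value} stratum")
    return AgreementRate(rate=num / den, numerator=num, denominator=den)


@dataclass(frozen=True)
class AgreementReport:
    """Stratified agreement rates plus chance-corrected kappa.

    ``kappa`` is a Cohen's-kappa extension computed on the same flow
    table (not part of the original agreement presentation).
    """

    overall: AgreementRate
    non_rejection: AgreementRate
    rejection: Optional[AgreementRate]
    exact_type: Optional[AgreementRate]
    kappa: Optional[float]
    n_total: int

    def to_dict(self) -> dict:
        def rate(r: Optional[AgreementRate]):
            if r is None:
                return None
            return {
                "percent": r.percent,
                "numerator": r.numerator,
                "denominator": r.denominator,
            }

        return {
            "n_total": self.n_total,
            "overall": rate(self.overall),
            "non_rejection": rate(self.non_rejection),
            "rejection": rate(self.rejection),
            "exact_type_within_rejection": rate(self.exact_type),
            "cohen_kappa_extension": self.kappa,
        }


def agreement_report(flow: FlowTable) -> AgreementReport:
    """Full agreement report; rejection strata are None when empty."""

    def maybe(stratum: Stratum) -> Optional[AgreementRate]:
        try:
            return agreement_rate(flow, stratum)
        except ValueError:
            return None

    try:
        kappa = cohen_kappa(flow)
    except ValueError:
        kappa = None
    return AgreementReport(
        overall=agreement_rate(flow, Stratum.OVERALL),
        non_rejection=maybe(Stratum.NON_REJECTION),
        rejection=maybe(Stratum.REJECTION),
        exact_type=maybe(Stratum.EXACT_TYPE),
        kappa=kappa,
        n_total=flow.n_total,
    )


def cohen_kappa(flow: FlowTable) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e), over base categories.

    Labels present on only one side contribute zero to both the observed
    and the expected diagonal.  Raises when p_e = 1 (kappa undefined).
    """
    n = flow.n_total
    if n < 1:
        raise ValueError("kappa undefined for an empty table")
    labels = [r for r in flow.rows if r in flow.cols]
    p_o = sum(flow.cell(l, l) for l in labels) / n
    rows_m = flow.row_marginals()
    cols_m = flow.col_marginals()
    p_e = sum(
        rows_m[_label_key(l)] * cols_m[_label_key(l)] for l in labels
    ) / (n * n)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class DiscrepancyPanels:
    """Row-level disagreements for one category family (AMR or TCMR).

    ``pathologist_only``: pathologist assigned the family, engine did not;
    ``engine_only``: engine assigned it, pathologist did not — the two
    panels of a published discrepancy table.
    """

    family: str
    pathologist_only: tuple[BiopsyRecord, ...]
    engine_only: tuple[BiopsyRecord, ...]


def discrepancy_records(
    records: Sequence[BiopsyRecord],
    engine: Optional[Mapping[str, DiagnosisCategory]] = None,
) -> list[BiopsyRecord]:
    """Records where pathologist and engine disagree at base-category level.

    Input order is preserved (published tables list pathologist-only
    cases first; use :func:`discrepancy_panels` for the partition).
    """
    engine_labels = _engine_labels(records, engine)
    out = []
    for rec, e in zip(records, engine_labels):
        p = _pathologist_label(rec)
        if not _base_match(p, e):
            out.append(rec)
    return out


def discrepancy_panels(
    records: Sequence[BiopsyRecord],
    family: str,
    engine: Optional[Mapping[str, DiagnosisCategory]] = None,
) -> DiscrepancyPanels:
    """Partition disagreements for one family ("AMR" or "TCMR")."""
    fam = {"AMR": _AMR_FAMILY, "TCMR": _TCMR_FAMILY}.get(family.upper())
    if fam is None:
        raise ValueError(f"unknown category family: {family!r}")
    engine_labels = _engine_labels(records, engine)
    path_only, eng_only = [], []
    for rec, e in zip(records, engine_labels):
        p = _pathologist_label(rec)
        p_in = isinstance(p, DiagnosisCategory) and p in fam
        e_in = e in fam
        if p_in and not e_in:
            path_only.append(rec)
        elif e_in and not p_in:
            eng_only.append(rec)
    return DiscrepancyPanels(
        family=family.upper(),
        pathologist_only=tuple(path_only),
        engine_only=tuple(eng_only),
    )
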
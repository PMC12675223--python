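import pytest

from banffdx.core import (
    Abo,
    BanffLesionScores,
    BiopsyRecord,
    ClinicalContext,
    Dsa,
)
from banffdx.io import Fixture, load_fixture


def make_scores(**kwargs) -> BanffLesionScores:
    """Score vector with unspecified lesions at 0 (not missing)."""
    base = dict.fromkeys(
        ("t", "t_ifta", "i", "i_ifta", "v", "g", "ptc",
         "c4d", "cg", "cv", "ci", "ct", "ptcbm"), 0
    )
    base.update(kwargs)
    return BanffLesionScores(**base)


def make_context(
    dsa: Dsa = Dsa.NEGATIVE, abo: Abo = Abo.COMPATIBLE, **kwargs
) -> ClinicalContext:
    return ClinicalContext(dsa=dsa, abo=abo, **kwargs)


def make_record(record_id="r1", scores=None, context=None, **kwargs) -> BiopsyRecord:
    return BiopsyRecord(
        record_id=record_id,
        patient_id=record_id,
        scores=scores if scores is not None else make_scores(),
        context=context if context is not None else make_context(),
        **kwargs,
    )


@pytest.fixture(scope="session")
def table1():
    return load_fixture(Fixture.TABLE1)


@pytest.fixture(scope="session")
def table2():
    return load_fixture(Fixture.TABLE2)


@pytest.fixture(scope="session")
def table1_by_id(table1):
    return {r.record_id: r for r in table1}


@pytest.fixture(scope="session")
def table2_by_id(table2):
    return {r.record_id: r for r in table2}
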
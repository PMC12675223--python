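"""Flow tables, stratified agreement, kappa, discrepancy extraction."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from banffdx.concordance import (
    OTHER,
    FlowTable,
    Stratum,
    agreement_rate,
    agreement_report,
    build_flow_table,
    cohen_kappa,
    discrepancy_panels,
    discrepancy_records,
)
from banffdx.core import DiagnosisCategory as C


def flow(rows, cols, counts):
    return FlowTable(rows=tuple(rows), cols=tuple(cols), counts=np.array(counts))


def identity_flow(labels, n_each=5):
    k = len(labels)
    return flow(labels, labels, np.eye(k, dtype=int) * n_each)


class TestFlowTable:
    def test_from_table1_fixture(self, table1):
        ft = build_flow_table(table1)
        assert ft.n_total == 27
        assert sum(ft.row_marginals().values()) == 27
        assert sum(ft.col_marginals().values()) == 27

    def test_empty_input(self):
        ft = build_flow_table([])
        assert ft.n_total == 0 and ft.counts.size == 0

    def test_identical_labels_aggregate(self, table1_by_id):
        rec = table1_by_id["T1-104553-2018-d380"]  # "No rejection" -> A-AMR
        two = [rec, rec.__class__(**{**rec.__dict__, "record_id": "copy"})]
        ft = build_flow_table(two)
        assert ft.cell(C.NO_REJECTION, C.A_AMR) == 2

    def test_missing_pathologist_label_names_record(self, table1_by_id):
        rec = table1_by_id["T1-104553-2018-d380"]
        bare = rec.__class__(**{**rec.__dict__, "pathologist_dx": None})
        with pytest.raises(ValueError, match=bare.record_id):
            build_flow_table([bare])

    def test_free_text_collapses_to_other(self, table1):
        ft = build_flow_table(table1)
        assert OTHER in ft.rows
        # PGNMID, FSGS x2, toxic tubulopathy, BKV, TMA
        assert ft.row_marginals()[OTHER] == 6

    def test_exports(self, table1, tmp_path):
        ft = build_flow_table(table1)
        csv_path = tmp_path / "flow.csv"
        ft.to_long_csv(csv_path)
        header = csv_path.read_text().splitlines()[0]
        assert header == "pathologist,engine,count"
        payload = ft.to_sankey_json(tmp_path / "flow.json")
        assert payload["n_total"] == 27
        assert sum(l["value"] for l in payload["links"]) == 27


class TestAgreementRate:
    def test_printed_rejection_arithmetic(self):
        """113 of 131 pathologist-rejection biopsies also engine-rejection
        gives 86.3%."""
        ft = flow(
            [C.A_AMR, C.NO_REJECTION],
            [C.A_AMR, C.CA_AMR, C.NO_REJECTION],
            [[87, 26, 18], [0, 0, 0]],
        )
        r = agreement_rate(ft, Stratum.REJECTION)
        assert (r.numerator, r.denominator) == (113, 131)
        assert r.percent == 86.3
        exact = agreement_rate(ft, Stratum.EXACT_TYPE)
        assert (exact.numerator, exact.denominator) == (87, 131)
        assert exact.percent == 66.4

    def test_printed_non_rejection_arithmetic(self):
        ft = flow(
            [C.NO_REJECTION],
            [C.NO_REJECTION, C.A_AMR],
            [[863, 23]],
        )
        r = agreement_rate(ft, Stratum.NON_REJECTION)
        assert (r.numerator, r.denominator) == (863, 886)
        assert r.percent == 97.4

    def test_identity_table_is_perfect(self):
        ft = identity_flow([C.A_AMR, C.BC, C.NO_REJECTION])
        for stratum in Stratum:
            assert agreement_rate(ft, stratum).rate == 1.0

    def test_zero_diagonal_overall_is_zero(self):
        ft = flow([C.A_AMR, C.BC], [C.A_AMR, C.BC], [[0, 3], [4, 0]])
        assert agreement_rate(ft, Stratum.OVERALL).rate == 0.0

    def test_empty_stratum_is_an_error(self):
        ft = identity_flow([C.NO_REJECTION])
        with pytest.raises(ValueError, match="rejection"):
            agreement_rate(ft, Stratum.REJECTION)

    def test_conservation_of_marginals(self, table1, table2):
        """Rejection and non-rejection denominators partition the cohort."""
        for recs in (table1, table2):
            ft = build_flow_table(recs)
            rej = agreement_rate(ft, Stratum.REJECTION)
            non = agreement_rate(ft, Stratum.NON_REJECTION)
            assert rej.denominator + non.denominator == ft.n_total


class TestCohenKappa:
    def test_identity_is_one(self):
        assert cohen_kappa(identity_flow([C.A_AMR, C.BC])) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        ft = flow([C.A_AMR, C.BC], [C.A_AMR, C.BC], [[25, 25], [25, 25]])
        assert cohen_kappa(ft) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        ft = flow([C.A_AMR, C.BC], [C.A_AMR, C.BC], [[40, 10], [10, 40]])
        assert cohen_kappa(ft) == pytest.approx(0.6)

    def test_degenerate_table_is_an_error(self):
        ft = flow([C.BC], [C.BC], [[7]])
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa(ft)

    def test_matches_sklearn_on_random_tables(self):
        """100 random small tables: kappa from the flow table equals the
        label-pair computation of an independent library."""
        rng = np.random.default_rng(20_19)
        labels = [C.A_AMR, C.A_TCMR, C.BC, C.IFTA, C.NO_REJECTION]
        checked = 0
        while checked < 100:
            k = int(rng.integers(2, len(labels) + 1))
            use = labels[:k]
            counts = rng.integers(0, 8, size=(k, k))
            if counts.sum() == 0:
                continue
            ft = flow(use, use, counts)
            pairs_p, pairs_e = [], []
            for a in range(k):
                for b in range(k):
                    pairs_p += [use[a].value] * counts[a, b]
                    pairs_e += [use[b].value] * counts[a, b]
            try:
                ours = cohen_kappa(ft)
            except ValueError:
                continue
            ref = cohen_kappa_score(pairs_p, pairs_e)
            assert ours == pytest.approx(ref, abs=1e-12)
            checked += 1


class TestDiscrepancies:
    def test_perfect_agreement_has_none(self, table1_by_id):
        rec = table1_by_id["T1-104553-2018-d380"]
        assert discrepancy_records(
            [rec], engine={rec.record_id: C.NO_REJECTION}
        ) == []

    def test_table1_panels(self, table1):
        """Against the reference labels, the 27 discrepancy records split
        14 pathologist-only / 13 engine-only for the AMR family."""
        reference = {r.record_id: r.expected_engine_dx for r in table1}
        assert len(discrepancy_records(table1, engine=reference)) == 27
        panels = discrepancy_panels(table1, "AMR", engine=reference)
        assert len(panels.pathologist_only) == 14
        assert len(panels.engine_only) == 13

    def test_table1_recomputed_differs_only_on_flagged_row(self, table1):
        """Recomputing with the engine, the one known-deviation row whose
        engine output coincides with the pathologist label drops out; every
        other disagreement is reproduced."""
        recomputed = {r.record_id for r in discrepancy_records(table1)}
        expected = {r.record_id for r in table1} - {"T1-104601-2019-d365"}
        assert recomputed == expected

    def test_table2_panels(self, table2):
        assert len(discrepancy_records(table2)) == 22
        panels = discrepancy_panels(table2, "TCMR")
        assert len(panels.pathologist_only) == 8
        assert len(panels.engine_only) == 14

    def test_order_preserved(self, table2):
        panels = discrepancy_panels(table2, "TCMR")
        ids = [r.record_id for r in panels.pathologist_only]
        assert ids == [r.record_id for r in table2[:8]]

    def test_unknown_family_is_an_error(self, table1):
        with pytest.raises(ValueError, match="family"):
            discrepancy_panels(table1, "XMR")


class TestAgreementReport:
    def test_report_structure(self, table2):
        rep = agreement_report(build_flow_table(table2))
        d = rep.to_dict()
        assert d["n_total"] == 22
        assert d["overall"]["denominator"] == 22
        assert "cohen_kappa_extension" in d
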
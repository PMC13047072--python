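import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cheilitis_pv.contingency import (
    ContingencyTable,
    build_cell_set,
    build_table,
    report_exposures,
    stratified_cells,
)
from cheilitis_pv.stratified import StratumSpec

from _oracles import brute_force_cells
from conftest import make_report


class TestBuildTable:
    def test_four_report_enumeration(self, four_report_corpus):
        t = build_table(four_report_corpus, "D", "E")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_repeated_mentions_count_once(self):
        r = make_report("c1", drugs=("D", "D"), events=("E",))
        t = build_table([r], "D", "E")
        assert t.a == 1

    def test_absent_drug_gives_a_zero(self, four_report_corpus):
        t = build_table(four_report_corpus, "NOPE", "E")
        assert t.a == 0
        assert t.n_total == 4

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(1, -1, 0, 0)

    def test_suspect_only_roles_narrow_exposure(self):
        r = make_report("c1", drugs=("D", "X"), events=("E",))  # X is concomitant
        assert build_table([r], "X", "E", roles="all").a == 1
        assert build_table([r], "X", "E", roles="suspect_only").a == 0

    @given(
        st.tuples(
            st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_transposition_swaps_b_and_c(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d, drug="D", event="E")
        tt = t.transpose()
        assert (tt.a, tt.b, tt.c, tt.d) == (a, c, b, d)


class TestCellSet:
    def test_closed_form_expectation(self, four_report_corpus):
        cells = build_cell_set(four_report_corpus, min_n=1)
        cell = next(c for c in cells if c.drug == "D" and c.event == "e")
        assert cell.n == 1
        assert cell.E == pytest.approx(2 * 2 / 4)

    def test_min_n_filters(self, four_report_corpus):
        assert build_cell_set(four_report_corpus, min_n=3) == []

    def test_empty_corpus(self):
        assert build_cell_set([], min_n=1) == []

    def test_agrees_with_brute_force(self, small_corpus):
        reports, _ = small_corpus
        subset = reports[:400]
        cells = {(c.drug, c.event): c for c in build_cell_set(subset, min_n=1)}
        brute = brute_force_cells(subset)
        assert set(cells) == set(brute)
        for pair, table in brute.items():
            assert cells[pair].n == table.a
            assert cells[pair].E == pytest.approx(table.expected_a)

    def test_total_n_conserved(self, small_corpus):
        reports, _ = small_corpus
        subset = reports[:500]
        cells = build_cell_set(subset, min_n=1)
        comentions = sum(
            len(ds) * len(es) for ds, es in report_exposures(subset)
        )
        assert sum(c.n for c in cells) == comentions

    def test_margins_preserved(self, small_corpus):
        # independence expectations preserve margins: the four cell
        # expectations of any pair's 2x2 sum to N, and E_a matches the
        # closed form (a+b)(a+c)/N
        reports, _ = small_corpus
        subset = reports[:500]
        n = len(subset)
        for drug, event in [("DRUG_000", "Cheilitis"), ("DRUG_001", "EVENT_003")]:
            t = build_table(subset, drug, event)
            e_a = t.n_drug * t.n_event / n
            e_b = t.n_drug * (n - t.n_event) / n
            e_c = (n - t.n_drug) * t.n_event / n
            e_d = (n - t.n_drug) * (n - t.n_event) / n
            assert e_a + e_b + e_c + e_d == pytest.approx(n)
            assert t.expected_a == pytest.approx(e_a)

    def test_relabeling_reports_leaves_e_invariant(self, small_corpus):
        reports, _ = small_corpus
        subset = reports[:200]
        shuffled = list(reversed(subset))
        a = {(c.drug, c.event): c.E for c in build_cell_set(subset)}
        b = {(c.drug, c.event): c.E for c in build_cell_set(shuffled)}
        assert a == b


class TestStratifiedCells:
    def test_single_stratum_reduces_to_crude(self, small_corpus):
        reports, _ = small_corpus
        subset = reports[:300]
        crude = {(c.drug, c.event): c for c in build_cell_set(subset)}
        strat = stratified_cells(subset, lambda r: "all")
        assert {(c.drug, c.event) for c in strat} == set(crude)
        for c in strat:
            assert c.E == pytest.approx(crude[(c.drug, c.event)].E)

    def test_identical_strata_match_unstratified(self):
        half = [
            make_report("a1", drugs=("D",), events=("E",)),
            make_report("a2", drugs=("D",), events=("X",)),
            make_report("a3", drugs=("Z",), events=("E",)),
            make_report("a4", drugs=("Z",), events=("X",)),
        ]
        other = [
            make_report(r.case_id + "b", drugs=tuple(d.name for d in r.drugs),
                        events=tuple(r.events))
            for r in half
        ]
        corpus = half + other
        labels = {r.case_id: ("s1" if not r.case_id.endswith("b") else "s2")
                  for r in corpus}
        crude = {(c.drug, c.event): c.E for c in build_cell_set(corpus)}
        strat = stratified_cells(corpus, lambda r: labels[r.case_id])
        for c in strat:
            assert c.E == pytest.approx(crude[(c.drug, c.event)])

    def test_confounded_stratum_shifts_expectation(self):
        # stratum 1: drug and event both common; stratum 2: both rare.
        # the stratum drives both margins, so the within-stratum baseline
        # absorbs the confounding: stratified E exceeds crude E, moving the
        # expectation toward the (confounding-inflated) observed count.
        s1 = [
            make_report(f"s1_{i}", drugs=("D",) if i < 8 else ("Z",),
                        events=("E",) if i < 8 else ("X",), age=30.0)
            for i in range(10)
        ]
        s2 = [
            make_report(f"s2_{i}", drugs=("D",) if i < 2 else ("Z",),
                        events=("E",) if i < 2 else ("X",), age=70.0)
            for i in range(10)
        ]
        corpus = s1 + s2
        crude = {(c.drug, c.event): c.E for c in build_cell_set(corpus)}
        strat = {
            (c.drug, c.event): c.E
            for c in stratified_cells(corpus, StratumSpec.age())
        }
        assert strat[("D", "e")] > crude[("D", "e")]

    def test_unknown_stratum_kept_unless_complete_case(self):
        r1 = make_report("c1", age=None)
        r2 = make_report("c2", age=30.0)
        with_unknown = stratified_cells([r1, r2], StratumSpec.age())
        assert sum(c.n for c in with_unknown) == 2
        cc = stratified_cells([r1, r2], StratumSpec.age(), complete_case=True)
        assert sum(c.n for c in cc) == 1
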
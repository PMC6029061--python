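"""Weight-matrix normalization, scoring, scanning and ranking."""

import pytest
from hypothesis import given, settings, strategies as st

from editomics.editome_io import SequenceRecord
from editomics.fixtures import FixtureSpec, make_editome
from editomics.targetscan import (
    BASES,
    ScanHit,
    WeightColumn,
    WeightMatrix,
    colour_code,
    matrix_from_tsv,
    matrix_to_tsv,
    max_score,
    normalize_column,
    scan,
    score_window,
)


class TestNormalizeColumn:
    def test_three_locks_fix_the_fourth(self):
        col = normalize_column({"A": 15, "C": 35, "G": 5})
        assert col.values == {"A": 15, "C": 35, "G": 5, "T": 45}

    def test_no_locks_gives_uniform_n(self):
        assert normalize_column({}).values == {b: 25 for b in BASES}

    def test_pyrimidine_bias_leaves_purines_zero(self):
        col = normalize_column({"C": 40, "T": 60})
        assert col.values == {"A": 0, "C": 40, "G": 0, "T": 60}

    def test_remainder_distributed_in_base_order(self):
        col = normalize_column({"A": 99})  # 1 left for C, G, T
        assert col.values == {"A": 99, "C": 1, "G": 0, "T": 0}

    def test_overfull_locks_rejected(self):
        with pytest.raises(ValueError):
            normalize_column({"A": 60, "C": 60})


def brute_force_score(window, matrix):
    """Independent per-position recomputation of the published score rule."""
    total = 0.0
    for base, col in zip(window, matrix.columns):
        total += col.values.get(base, 0) * col.weight / 100
    return total


class TestScoreWindow:
    def test_matches_brute_force_on_arbitrary_windows(self, ppr98_matrix):
        windows = ["A" * 23, "C" * 23, ("ACGT" * 6)[:23]]
        for w in windows:
            total, per = score_window(w, ppr98_matrix)
            assert total == pytest.approx(brute_force_score(w, ppr98_matrix))
            assert total == pytest.approx(sum(per))

    def test_n_scores_zero(self):
        m = WeightMatrix([WeightColumn({"A": 100, "C": 0, "G": 0, "T": 0})])
        assert score_window("N", m)[0] == 0

    def test_length_mismatch_rejected(self, ppr98_matrix):
        with pytest.raises(ValueError):
            score_window("ACGT", ppr98_matrix)

    def test_zero_weight_matrix_scores_zero(self):
        m = WeightMatrix([WeightColumn({b: 25 for b in BASES}, weight=0)] * 3)
        assert score_window("ACG", m)[0] == 0


@settings(derandomize=True, max_examples=100)
@given(
    st.text(alphabet="ACGT", min_size=5, max_size=5),
    st.lists(
        st.tuples(
            st.integers(0, 100), st.integers(0, 100), st.integers(0, 100),
            st.integers(0, 300),
        ),
        min_size=5, max_size=5,
    ),
)
def test_score_window_equals_oracle_property(window, raw_cols):
    cols = []
    for a, c, g, w in raw_cols:
        # renormalise the three draws into a valid 100-sum column
        total = a + c + g
        if total > 100:
            a, c, g = a * 100 // (total or 1), 0, 0
        cols.append(WeightColumn({"A": a, "C": c, "G": g, "T": 100 - a - c - g}, weight=w))
    m = WeightMatrix(cols)
    total, per = score_window(window, m)
    assert total == pytest.approx(brute_force_score(window, m))
    assert max_score(m) >= total


class TestScan:
    def test_genome_mode_equals_brute_force_enumeration(self):
        seq = "ACGTACGTAC"  # 10 bp, 3-column matrix -> 8 windows per strand
        m = WeightMatrix([
            normalize_column({"A": 70, "C": 10, "G": 10}),
            normalize_column({"G": 100}),
            normalize_column({"T": 50, "C": 30}),
        ])
        hits = scan([SequenceRecord("s", seq)], m, mode="genome", strand="+")
        assert len(hits) == 8
        expected = {i + 1: brute_force_score(seq[i : i + 3], m) for i in range(8)}
        for h in hits:
            assert h.total == pytest.approx(expected[h.start])

    def test_tie_inclusive_ranking(self):
        # engineered scores {9,7,7,7,3}: top_n=2 with ties returns 4 hits
        m = WeightMatrix([normalize_column({"A": 9, "C": 7, "G": 3, "T": 81},
                                           weight=100)])
        seq = "ACCCG"
        hits = scan([SequenceRecord("s", seq)], m, mode="genome", strand="+",
                    top_n=2, include_ties=True)
        assert [h.total for h in hits] == [9, 7, 7, 7]
        strict = scan([SequenceRecord("s", seq)], m, mode="genome", strand="+",
                      top_n=2, include_ties=False)
        assert len(strict) == 2

    def test_edit_anchored_one_window_per_edit(self):
        editome, _ = make_editome(FixtureSpec(seed=1, n_genes=1, edits_per_gene=2))
        m = WeightMatrix([
            normalize_column({"T": 100}),
            WeightColumn({b: 25 for b in BASES}, weight=0, is_anchor=True),
            normalize_column({"A": 40}),
        ])
        hits = scan([editome], m, mode="edit_anchored")
        assert len(hits) == 2
        # the anchor sits over the genomically unedited pyrimidine
        for h in hits:
            assert h.window[1] in "CT"

    def test_edit_anchored_requires_anchor(self):
        editome, _ = make_editome(FixtureSpec(seed=1, n_genes=1))
        m = WeightMatrix([normalize_column({})])
        with pytest.raises(ValueError, match="anchor"):
            scan([editome], m, mode="edit_anchored")

    def test_cds_mode_scans_sense_sequence_only(self, default_editome):
        editome, _ = default_editome
        m = WeightMatrix([normalize_column({"A": 100})] * 3)
        hits = scan([editome], m, mode="cds")
        total_windows = sum(
            len(editome.cds_sequence(c)) - 2 for c in editome.cds_features()
        )
        assert len(hits) == total_windows
        assert all(h.strand == "+" for h in hits)

    def test_ranking_stable_under_source_permutation(self):
        m = WeightMatrix([normalize_column({"G": 90})] * 2)
        a, b = SequenceRecord("a", "GGGGAA"), SequenceRecord("b", "AAGGGG")
        h1 = scan([a, b], m, strand="+")
        h2 = scan([b, a], m, strand="+")
        assert [(h.source_id, h.start, h.total) for h in h1] == [
            (h.source_id, h.start, h.total) for h in h2
        ]

    def test_circular_topology_wraps_where_linear_skips(self):
        m = WeightMatrix([normalize_column({"A": 100})] * 3)
        lin = scan([SequenceRecord("l", "AAAA")], m, strand="+")
        ed_circ = SequenceRecord("c", "AAAA", topology="circular")
        circ = scan([ed_circ], m, strand="+")
        assert len(lin) == 2 and len(circ) == 4

    def test_bonus_applied_only_on_anchor_cytidine(self):
        m = WeightMatrix([
            normalize_column({"A": 100}),
            WeightColumn({b: 25 for b in BASES}, weight=0, is_anchor=True),
        ])
        hits = scan([SequenceRecord("s", "ACAT")], m, strand="+", edit_bonus=200)
        by_start = {h.start: h for h in hits}
        assert by_start[1].bonus_applied and by_start[1].total == 300
        assert not by_start[3].bonus_applied and by_start[3].total == 100


class TestMaxScore:
    def test_uniform_matrix(self):
        m = WeightMatrix([normalize_column({})] * 4)
        assert max_score(m) == 100

    def test_bonus_requires_anchor(self):
        m = WeightMatrix([normalize_column({})])
        assert max_score(m, edit_bonus=200) == 25  # no anchor: bonus ignored


class TestColourCode:
    def test_green_red_and_skipped_columns(self):
        m = WeightMatrix([
            normalize_column({"A": 70, "C": 10, "G": 10}),  # T gets 10
            WeightColumn({b: 25 for b in BASES}, weight=0),
        ])
        hit_best = ScanHit("s", 1, "+", "AA", *reversed(score_window("AA", m)))
        hit_worst = ScanHit("s", 1, "+", "CA", *reversed(score_window("CA", m)))
        assert colour_code(hit_best, m)[0] == "green"
        assert colour_code(hit_worst, m)[0] == "red"
        assert colour_code(hit_best, m)[1] is None


def test_matrix_tsv_round_trip(ppr98_matrix):
    text = matrix_to_tsv(ppr98_matrix)
    again = matrix_from_tsv(text)
    assert [c.values for c in again.columns] == [c.values for c in ppr98_matrix.columns]
    assert [c.weight for c in again.columns] == [c.weight for c in ppr98_matrix.columns]
    assert again.anchor_index == ppr98_matrix.anchor_index
    assert matrix_to_tsv(again) == text
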
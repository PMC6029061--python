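"""Homology-based editing-site prediction: cells, commons, modes."""

import itertools

import pytest

from editomics.editome_io import SequenceRecord
from editomics.fixtures import FixtureSpec, make_editome, _revcomp
from editomics.nomenclature import Direction, translate_codon
from editomics.prediction import (
    AlignedColumn,
    AlignedRow,
    BOTH_DIRECTIONS,
    PredictionCell,
    RefCodon,
    alignment_mode,
    annotate_query,
    call_edits_from_cdna,
    cell_display,
    commons,
    commons_to_frame,
    editable_codons,
    predict,
    predict_cell,
    reference_proteins,
    translated_search,
)


def brute_editable(codon, direction):
    """Independent enumeration over all single-base substitutions chains."""
    src = "C" if direction is Direction.C_TO_U else "T"
    dst = "T" if direction is Direction.C_TO_U else "C"
    pos = [i for i, b in enumerate(codon) if b == src]
    out = set()
    for r in range(1, len(pos) + 1):
        for sub in itertools.combinations(pos, r):
            lst = list(codon)
            for i in sub:
                lst[i] = dst
            out.add("".join(lst))
    out.discard(codon)
    return out


class TestEditableCodons:
    def test_cca_forward(self):
        assert editable_codons("CCA", Direction.C_TO_U) == {"TCA", "CTA", "TTA"}

    def test_no_convertible_base(self):
        assert editable_codons("AAA", Direction.C_TO_U) == set()

    def test_taa_reverse_matches_enumeration(self):
        got = editable_codons("TAA", Direction.U_TO_C)
        assert got == brute_editable("TAA", Direction.U_TO_C)
        assert "CAA" in got  # the stop-removing glutamine codon

    @pytest.mark.parametrize("direction", list(Direction))
    def test_all_codons_match_brute_force(self, direction):
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            assert editable_codons(codon, direction) == brute_editable(codon, direction)


def ref_column(codon_before, codon_after, edited):
    from editomics.editome_io import AnnotatedEdit
    from editomics.nomenclature import EditingSite

    edits = []
    if edited and codon_before != codon_after:
        edits = [AnnotatedEdit(
            site=EditingSite("g", 1, Direction.C_TO_U, codon_before, codon_after),
            record_id="r", genome_pos=1,
        )]
    return AlignedColumn(
        query_codon_start=1,
        query_codon="NNN",
        ref_codon_index=1,
        ref=RefCodon(
            codon_before=codon_before,
            codon_after=codon_after,
            aa_genomic=translate_codon(codon_before),
            aa_edited=translate_codon(codon_after),
            edits=edits,
        ),
    )


class TestPredictCell:
    def test_pre_edited_reference(self):
        # query ACT (T) vs reference isoleucine encoded genomically:
        # convertible by editing codon position 2 (ACT -> ATT)
        cell = predict_cell("ACT", ref_column("ATT", "ATT", edited=False))
        assert cell.status == "pre_edited_in_ref"
        assert cell.required_query_edits == frozenset({2})
        assert cell.direction is Direction.C_TO_U

    def test_edited_reference(self):
        cell = predict_cell("TCA", ref_column("TCA", "TTA", edited=True))
        assert cell.status == "edited_in_ref"
        assert cell.converted_codon == "TTA"

    def test_no_homology_is_hyphen(self):
        cell = predict_cell("TCA", None)
        assert cell.status == "no_homology"
        assert cell_display(cell) == "-"

    def test_unedited_retained(self):
        cell = predict_cell("TTA", ref_column("TCA", "TTA", edited=True))
        assert cell.status == "unedited_retained"

    def test_inconvertible(self):
        cell = predict_cell("GGG", ref_column("AAA", "AAA", edited=False))
        assert cell.status == "inconvertible"
        assert cell_display(cell) == "K"

    def test_consistent_with_editable_codons_for_all_codons(self):
        """Small-instance oracle: status assignment over all 64 codons x 20
        amino acids agrees with a re-enumeration of convertibility."""
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            for target_codon in ("TTA", "ATT", "CGA", "GGG"):
                target_aa = translate_codon(target_codon)
                cell = predict_cell(codon, ref_column(target_codon, target_codon, False))
                reachable = {
                    translate_codon(c)
                    for d in BOTH_DIRECTIONS
                    for c in brute_editable(codon, d)
                }
                if translate_codon(codon) == target_aa:
                    assert cell.status == "unedited_retained"
                elif target_aa in reachable:
                    assert cell.status == "pre_edited_in_ref"
                else:
                    assert cell.status == "inconvertible"


def make_cells(statuses, **kw):
    cells = {}
    for i, status in enumerate(statuses):
        cells[f"ref{i}"] = PredictionCell(
            status=status,
            ref_aa="L" if status != "no_homology" else "-",
            required_query_edits=frozenset({2}) if status in (
                "edited_in_ref", "pre_edited_in_ref") else frozenset(),
            direction=Direction.C_TO_U if status in (
                "edited_in_ref", "pre_edited_in_ref") else None,
            converted_codon="TTA" if status in (
                "edited_in_ref", "pre_edited_in_ref") else "",
            ref_source=f"ref{i}", gene="atp9", ref_codon_index=31,
        )
    return {("+", 91, "TCA"): cells}


class TestCommons:
    def test_support_above_threshold(self):
        cells = make_cells(["pre_edited_in_ref"] * 8 + ["unedited_retained"] * 2)
        rows = commons(cells, threshold_percent=70)
        assert len(rows) == 1
        assert rows[0].support_percent == 80.0
        assert rows[0].included_by == "threshold"
        assert rows[0].label == "atp9eU92SL"

    def test_below_threshold_rescued_by_reference_site_option(self):
        statuses = (["edited_in_ref"] + ["pre_edited_in_ref"] * 3
                    + ["unedited_retained"] * 6)
        assert commons(make_cells(statuses), threshold_percent=70) == []
        rows = commons(make_cells(statuses), threshold_percent=70,
                       always_include_reference_sites=True)
        assert len(rows) == 1 and rows[0].included_by == "reference_site_option"

    def test_no_homology_excluded_from_denominator(self):
        cells = make_cells(["pre_edited_in_ref"] * 7 + ["no_homology"] * 3)
        rows = commons(cells, threshold_percent=70)
        assert rows[0].support_percent == 100.0

    def test_only_known_sites_drops_pre_edited_only_rows(self):
        cells = make_cells(["pre_edited_in_ref"] * 10)
        assert commons(cells, only_known_sites=True) == []
        cells = make_cells(["edited_in_ref"] + ["pre_edited_in_ref"] * 9)
        assert len(commons(cells, only_known_sites=True)) == 1

    def test_stop_removal_prognosis_adds_reverse_row(self):
        cells = {("+", 91, "TGA"): {
            "ref0": PredictionCell(status="inconvertible", ref_aa="K",
                                   ref_source="ref0", gene="atp9",
                                   ref_codon_index=31)}}
        rows = commons(cells, stop_removal_prognosis=True)
        assert len(rows) == 1
        row = rows[0]
        assert row.direction is Direction.U_TO_C
        assert row.query_codon_after == "CGA"  # TGA -> CGA restores arginine
        assert translate_codon(row.query_codon_after) == "R"
        assert row.included_by == "stop_removal"

    def test_threshold_monotonicity(self):
        cells = make_cells(["pre_edited_in_ref"] * 5 + ["unedited_retained"] * 5)
        all_rows = {r.label for r in commons(cells, threshold_percent=0)}
        for t in (30, 50, 80, 100):
            assert {r.label for r in commons(cells, threshold_percent=t)} <= all_rows

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            commons({}, threshold_percent=120)


class TestTranslatedSearch:
    def test_self_hit_full_length_identity(self, default_editome, self_query):
        editome, _ = default_editome
        hits = translated_search(self_query, [editome])
        genes = {h.gene for h in hits}
        assert genes == {c.gene for c in editome.cds_features()}
        # mismatches only at edited codons
        for h in hits:
            n_edited = sum(1 for c in h.protein.codons if c.edited)
            assert h.identity >= 1 - (n_edited + 1) / len(h.columns)

    def test_scrambled_query_has_no_hit(self, default_editome):
        import random

        editome, _ = default_editome
        rng = random.Random(0)
        seq = list(editome.records[0].seq)
        rng.shuffle(seq)
        hits = translated_search(SequenceRecord("scrambled", "".join(seq)), [editome])
        assert hits == []

    def test_empty_reference_selection_rejected(self, self_query):
        with pytest.raises(ValueError):
            translated_search(self_query, [])


class TestPredictPipeline:
    def test_self_prediction_recovers_all_edits_at_full_support(
        self, default_editome, self_query
    ):
        editome, _ = default_editome
        rows, _ = predict(self_query, [editome])
        assert sorted(r.label for r in rows) == sorted(
            e.site.label for e in editome.applied_edits()
        )
        for r in rows:
            assert r.support_percent == 100.0
            assert all(c.status == "edited_in_ref" for c in r.cells.values())

    def test_strand_symmetry(self, default_editome):
        editome, _ = default_editome
        fwd = SequenceRecord("q", editome.records[0].seq)
        rev = SequenceRecord("q", _revcomp(editome.records[0].seq))
        r1, _ = predict(fwd, [editome])
        r2, _ = predict(rev, [editome])
        assert sorted(r.label for r in r1) == sorted(r.label for r in r2)

    def test_commons_frame_and_annotated_genbank(self, default_editome, self_query):
        from editomics.editome_io import parse_genbank, write_genbank

        editome, _ = default_editome
        rows, _ = predict(self_query, [editome])
        frame = commons_to_frame(rows, [editome.id])
        assert all(v.startswith("RED:") for v in frame[editome.id])
        annotated = annotate_query(self_query, rows)
        again = parse_genbank(write_genbank(annotated))
        feats = [f for f in again.features if f.kind == "RNA_editing"]
        assert len(feats) == len(rows)
        assert all(f.qualifier("applied") == "no" for f in feats)


class TestAlignmentMode:
    def _gene_alignment(self, editome):
        cds = editome.cds_features()[0]
        return cds, editome.cds_sequence(cds)

    def test_reference_edit_maps_through_gap_columns(self, default_editome):
        editome, _ = default_editome
        cds, seq = self._gene_alignment(editome)
        edit_pos = min(e.site.cds_pos for e in editome.applied_edits()
                       if e.site.gene == cds.gene)
        # insert a gap triple upstream of the edit in the reference row
        gcol = 3
        ref_row = seq[:gcol] + "---" + seq[gcol:]
        query_row = seq[:gcol] + "AAA" + seq[gcol:]
        res = alignment_mode(
            [AlignedRow(editome.id, ref_row), AlignedRow("q", query_row)],
            {editome.id: editome},
        )
        expected_col = edit_pos - 1 + 3  # shifted by the gap
        assert expected_col in res["edits_by_column"]
        assert ("q", expected_col) in res["matrix"]
        assert res["matrix"][("q", expected_col)].status == "edited_in_ref"

    def test_share_threshold_shading(self, default_editome):
        editome, _ = default_editome
        cds, seq = self._gene_alignment(editome)
        rows = [AlignedRow(editome.id, seq), AlignedRow("q1", seq), AlignedRow("q2", seq)]
        res2 = alignment_mode(rows, {editome.id: editome}, share_threshold=2)
        res4 = alignment_mode(rows, {editome.id: editome}, share_threshold=4)
        assert res2["shaded_columns"] == sorted(res2["edits_by_column"])
        assert res4["shaded_columns"] == []  # 1 ref + 2 predictions < 4

    def test_unequal_rows_rejected(self, default_editome):
        editome, _ = default_editome
        with pytest.raises(ValueError):
            alignment_mode(
                [AlignedRow("a", "ACGT"), AlignedRow("b", "ACG")], {}
            )


class TestCdnaMode:
    def test_atp9_fixture_reproduces_published_label(self):
        # serine codon 31 (cds 91-93) edited at position 92 to leucine
        codons = ["ATG"] + ["GCT"] * 29 + ["TCA"] + ["GCT"] * 9 + ["TAA"]
        genomic = "".join(codons)
        cdna = genomic[:91] + "T" + genomic[92:]
        sites, mismatches = call_edits_from_cdna(genomic, cdna, "atp9")
        assert [s.label for s in sites] == ["atp9eU92SL"]
        assert mismatches == []

    def test_identical_sequences_yield_nothing(self):
        sites, mismatches = call_edits_from_cdna("ATGTCATAA", "ATGTCATAA", "g")
        assert sites == [] and mismatches == []

    def test_silent_third_position_site(self):
        sites, _ = call_edits_from_cdna("ATGGCCTAA", "ATGGCTTAA", "g")
        assert len(sites) == 1
        assert sites[0].classification().silent

    def test_non_editing_mismatch_reported_separately(self):
        sites, mismatches = call_edits_from_cdna("ATGGCATAA", "ATGGGATAA", "g")
        assert sites == [] and mismatches == [(5, "C", "G")]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_edits_from_cdna("ATG", "ATGTCA", "g")

    def test_double_edit_in_one_codon_shares_codon_after(self):
        sites, _ = call_edits_from_cdna("ATGCCATAA", "ATGTTATAA", "g")
        assert [s.cds_pos for s in sites] == [4, 5]
        assert all(s.codon_after == "TTA" for s in sites)
        assert [s.label for s in sites] == ["geU4PL", "geU5PL"]


def test_reference_proteins_backmap(default_editome):
    editome, _ = default_editome
    for prot in reference_proteins(editome):
        assert len(prot.genomic_protein) == len(prot.edited_protein)
        for i, codon in enumerate(prot.codons):
            if codon.aa_genomic != codon.aa_edited:
                assert codon.edits, f"{prot.gene} codon {i + 1} lacks its edit record"
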
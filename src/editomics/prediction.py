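"""Homology-based prediction of candidate editing sites.

The core idea: a codon of an unannotated query is a candidate editing site
when converting some subset of its C positions to U (or T to C for reverse
editing) yields the amino acid that homologous references encode at the
orthologous position.  A prediction is stronger (shown RED) when the
reference itself reaches that amino acid through a documented editing event,
and weaker (BLACK) when the reference encodes it genomically ("pre-edited").
References that retain the unedited amino acid or hold an inconvertible
codon still display their amino acid; a hyphen is reserved for lacking
homology.  Per-site support across references is aggregated into the
*commons* table and filtered by a support threshold (default 70%).

The translated search is a six-frame translation of the query locally
aligned (affine gaps, BLOSUM62) against every reference's edited protein,
replacing an external BLASTX step.  Alignment and cDNA comparison modes for
pre-aligned homologous sequences are also provided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from editomics.editome_io import (
    AnnotatedEdit,
    Editome,
    Feature,
    Interval,
    SequenceRecord,
)
from editomics.nomenclature import (
    Direction,
    EditingSite,
    make_label,
    translate_codon,
)

__all__ = [
    "SearchParams",
    "ReferenceProtein",
    "PredictionCell",
    "CommonsRow",
    "editable_codons",
    "reference_proteins",
    "translated_search",
    "predict_cell",
    "commons",
    "predict",
    "alignment_mode",
    "call_edits_from_cdna",
    "commons_to_frame",
    "cell_display",
    "annotate_query",
]

BOTH_DIRECTIONS = (Direction.C_TO_U, Direction.U_TO_C)


def editable_codons(codon: str, direction: Direction) -> set[str]:
    """All codons reachable by editing a non-empty subset of convertible
    positions (C->T for C_to_U, T->C for U_to_C); the input codon excluded."""
    direction = Direction(direction)
    codon = codon.upper().replace("U", "T")
    src, dst = direction.genomic_base, direction.edited_base
    pos = [i for i, b in enumerate(codon) if b == src]
    out = set()
    for r in range(1, len(pos) + 1):
        for subset in itertools.combinations(pos, r):
            lst = list(codon)
            for i in subset:
                lst[i] = dst
            out.add("".join(lst))
    out.discard(codon)
    return out


# ---------------------------------------------------------------------------
# reference proteins


@dataclass
class RefCodon:
    """One reference codon with its editing state."""

    codon_before: str
    codon_after: str
    aa_genomic: str
    aa_edited: str
    edits: list[AnnotatedEdit] = field(default_factory=list)

    @property
    def edited(self) -> bool:
        return self.aa_genomic != self.aa_edited or bool(self.edits)


@dataclass
class ReferenceProtein:
    """A reference gene's protein before and after applying its edits."""

    gene: str
    source_id: str
    genomic_protein: str
    edited_protein: str
    codons: list[RefCodon]
    transl_table: int = 1

    def __post_init__(self) -> None:
        assert len(self.genomic_protein) == len(self.edited_protein)


def reference_proteins(editome: Editome) -> list[ReferenceProtein]:
    """Build per-gene reference proteins from an annotated editome."""
    known = {r.id.split(".")[0] for r in editome.records}
    out = []
    for cds in editome.cds_features():
        if any(iv.ref and iv.ref.split(".")[0] not in known for iv in cds.location):
            continue
        gene = cds.gene or cds.record_id
        seq = editome.cds_sequence(cds)
        codon_start = int(cds.qualifier("codon_start", "1"))
        seq = seq[codon_start - 1 :]
        seq = seq[: len(seq) - len(seq) % 3]
        if not seq:
            continue
        table = int(cds.qualifier("transl_table", "1"))
        edits_here = [
            e
            for e in editome.applied_edits()
            if e.site.gene == gene and e.feature is not None
        ]
        edited_seq = list(seq)
        for e in edits_here:
            p = e.site.cds_pos - 1
            if 0 <= p < len(edited_seq):
                edited_seq[p] = e.site.direction.edited_base
        edited_seq = "".join(edited_seq)
        codons = []
        for i in range(0, len(seq), 3):
            cb, ca = seq[i : i + 3], edited_seq[i : i + 3]
            codons.append(
                RefCodon(
                    codon_before=cb,
                    codon_after=ca,
                    aa_genomic=translate_codon(cb, table) if "N" not in cb else "X",
                    aa_edited=translate_codon(ca, table) if "N" not in ca else "X",
                    edits=[e for e in edits_here if i < e.site.cds_pos <= i + 3],
                )
            )
        out.append(
            ReferenceProtein(
                gene=gene,
                source_id=editome.id,
                genomic_protein="".join(c.aa_genomic for c in codons),
                edited_protein="".join(c.aa_edited for c in codons),
                codons=codons,
                transl_table=table,
            )
        )
    return out


# ---------------------------------------------------------------------------
# translated search


@dataclass
class SearchParams:
    """Configuration for the translated homology search."""

    min_score: float = 60.0
    min_identity: float = 0.35
    open_gap: float = -11.0
    extend_gap: float = -1.0
    matrix: str = "BLOSUM62"


@dataclass
class AlignedColumn:
    """One matched column: query codon vs reference codon information."""

    query_codon_start: int  # 1-based sense-orientation coordinate of first base
    query_codon: str  # sense orientation
    ref_codon_index: int  # 1-based codon in the reference CDS
    ref: RefCodon


@dataclass
class AlignmentHit:
    query_id: str
    ref_source: str
    gene: str
    score: float
    identity: float
    strand: str
    frame: int
    columns: list[AlignedColumn]
    protein: ReferenceProtein


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.open_gap
    aligner.extend_gap_score = params.extend_gap
    return aligner


def _six_frames(seq: str):
    """Yield (strand, frame_offset, protein) for all six reading frames."""
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            yield strand, off, s, prot


def translated_search(
    query: SequenceRecord,
    refs: list[Editome],
    params: SearchParams | None = None,
) -> list[AlignmentHit]:
    """Six-frame translated local alignment of a query against every
    reference edited protein.  Alignments below the score or identity floor
    are discarded.  Within each reference, overlapping hits on the same
    query region keep only the best score (tie-break by gene name)."""
    if not refs:
        raise ValueError("empty reference selection")
    params = params or SearchParams()
    aligner = _make_aligner(params)
    hits: list[AlignmentHit] = []
    if len(query.seq) < 3:
        return hits
    frames = list(_six_frames(query.seq))
    for ed in refs:
        for prot in reference_proteins(ed):
            if not prot.edited_protein:
                continue
            for strand, off, oriented, qprot in frames:
                if not qprot:
                    continue
                alns = aligner.align(qprot, prot.edited_protein)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                if aln.score < params.min_score:
                    continue
                columns: list[AlignedColumn] = []
                n_match = n_cols = 0
                for (qs, qe), (rs, re_) in zip(*aln.aligned):
                    for k in range(qe - qs):
                        qi, ri = qs + k, rs + k
                        n_cols += 1
                        if qprot[qi] == prot.edited_protein[ri]:
                            n_match += 1
                        codon = oriented[off + 3 * qi : off + 3 * qi + 3]
                        sense_start0 = off + 3 * qi
                        columns.append(
                            AlignedColumn(
                                query_codon_start=sense_start0 + 1,
                                query_codon=codon,
                                ref_codon_index=ri + 1,
                                ref=prot.codons[ri],
                            )
                        )
                identity = n_match / n_cols if n_cols else 0.0
                if identity < params.min_identity or not columns:
                    continue
                hits.append(
                    AlignmentHit(
                        query_id=query.id,
                        ref_source=ed.id,
                        gene=prot.gene,
                        score=float(aln.score),
                        identity=identity,
                        strand=strand,
                        frame=off,
                        columns=columns,
                        protein=prot,
                    )
                )
    # per reference and query region, highest score wins (tie: ref id, gene)
    hits.sort(key=lambda h: (-h.score, h.ref_source, h.gene))
    kept: list[AlignmentHit] = []
    covered: dict[str, set[tuple[str, int]]] = {}
    for h in hits:
        span = {(h.strand, c.query_codon_start) for c in h.columns}
        seen = covered.setdefault(h.ref_source, set())
        if span & seen:
            continue
        seen |= span
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# per-cell prediction


@dataclass
class PredictionCell:
    """Verdict of one reference about one query codon."""

    status: str  # edited_in_ref | pre_edited_in_ref | unedited_retained | inconvertible | no_homology
    ref_aa: str = "-"
    required_query_edits: frozenset[int] = frozenset()  # positions 1..3 within the codon
    direction: Direction | None = None
    converted_codon: str = ""
    ref_source: str = ""
    gene: str = ""
    ref_codon_index: int = 0
    align_score: float = 0.0
    factor_ids: list[int] = field(default_factory=list)

    @property
    def predicting(self) -> bool:
        return self.status in ("edited_in_ref", "pre_edited_in_ref")


PREDICTING = ("edited_in_ref", "pre_edited_in_ref")


def _best_conversion(
    query_codon: str, target_aa: str, directions, transl_table: int = 1
) -> tuple[Direction, frozenset[int], str] | None:
    """Cheapest conversion of query_codon to a codon translating to
    target_aa; ties break by direction order then codon lexicographically."""
    best = None
    for d in directions:
        d = Direction(d)
        for cand in sorted(editable_codons(query_codon, d)):
            if translate_codon(cand, transl_table) != target_aa:
                continue
            changed = frozenset(
                i + 1 for i, (a, b) in enumerate(zip(query_codon, cand)) if a != b
            )
            key = (len(changed), BOTH_DIRECTIONS.index(d), cand)
            if best is None or key < best[0]:
                best = (key, d, changed, cand)
    if best is None:
        return None
    return best[1], best[2], best[3]


def predict_cell(
    query_codon: str,
    column: AlignedColumn | None,
    directions=BOTH_DIRECTIONS,
    transl_table: int = 1,
) -> PredictionCell:
    """Classify one query codon against one reference column."""
    if column is None:
        return PredictionCell(status="no_homology", ref_aa="-")
    ref = column.ref
    ref_aa = ref.aa_edited
    query_codon = query_codon.upper().replace("U", "T")
    base = dict(
        ref_aa=ref_aa,
        ref_codon_index=column.ref_codon_index,
        factor_ids=[i for e in ref.edits for i in e.site.db_xrefs],
    )
    if "N" in query_codon or len(query_codon) != 3:
        return PredictionCell(status="inconvertible", **base)
    query_aa = translate_codon(query_codon, transl_table)
    if query_aa == ref_aa:
        return PredictionCell(status="unedited_retained", **base)
    conv = _best_conversion(query_codon, ref_aa, directions, transl_table)
    if conv is None:
        return PredictionCell(status="inconvertible", **base)
    d, changed, cand = conv
    status = "edited_in_ref" if ref.edited else "pre_edited_in_ref"
    return PredictionCell(
        status=status,
        required_query_edits=changed,
        direction=d,
        converted_codon=cand,
        **base,
    )


# ---------------------------------------------------------------------------
# commons aggregation


@dataclass
class CommonsRow:
    """One candidate edited nucleotide aggregated across references."""

    label: str
    gene: str
    direction: Direction
    query_codon_start: int  # 1-based sense coordinate of the codon's first base
    strand: str
    codon_position: int  # 1..3, the edited nucleotide within the codon
    query_codon_before: str
    query_codon_after: str
    cells: dict[str, PredictionCell]
    support_percent: float
    included_by: str  # threshold | reference_site_option | stop_removal
    factor_links: list[int] = field(default_factory=list)

    @property
    def cds_pos(self) -> int:
        from editomics.nomenclature import parse_label

        return parse_label(self.label)[1]


def _lead_cell(cells: dict[str, PredictionCell]) -> PredictionCell | None:
    preds = [c for c in cells.values() if c.predicting]
    if not preds:
        return None
    order = {"edited_in_ref": 0, "pre_edited_in_ref": 1}
    preds.sort(key=lambda c: (order[c.status], -c.align_score, c.ref_source, c.gene))
    return preds[0]


def commons(
    cells_by_codon: dict[tuple[str, int, str], dict[str, PredictionCell]],
    threshold_percent: float = 70.0,
    only_known_sites: bool = False,
    always_include_reference_sites: bool = False,
    directions=BOTH_DIRECTIONS,
    stop_removal_prognosis: bool = False,
    transl_table: int = 1,
) -> list[CommonsRow]:
    """Aggregate per-reference cells into filtered commons rows.

    ``cells_by_codon`` maps (strand, query_codon_start, query_codon) to a
    per-reference-id cell map.  Support is the percentage of predicting
    references among those with homology at the column.  Rows at or above
    ``threshold_percent`` are included by the threshold; below it, rows with
    at least one reference edited at the site survive only with
    ``always_include_reference_sites``.  ``only_known_sites`` keeps only
    rows with at least one edited reference.  ``stop_removal_prognosis``
    adds reverse-editing rows for every query stop codon convertible to a
    sense codon, regardless of reference support.
    """
    if not 0 <= threshold_percent <= 100:
        raise ValueError(f"threshold must be in [0, 100], got {threshold_percent}")
    directions = tuple(Direction(d) for d in directions)
    rows: list[CommonsRow] = []
    for (strand, qstart, qcodon), cells in sorted(cells_by_codon.items()):
        homologous = [c for c in cells.values() if c.status != "no_homology"]
        predicting = [c for c in homologous if c.predicting]
        has_ref_site = any(c.status == "edited_in_ref" for c in homologous)
        support = 100.0 * len(predicting) / len(homologous) if homologous else 0.0

        emit = None
        if predicting:
            if support >= threshold_percent:
                emit = "threshold"
            elif always_include_reference_sites and has_ref_site:
                emit = "reference_site_option"
        if emit and only_known_sites and not has_ref_site:
            emit = None
        if emit:
            lead = _lead_cell(cells)
            usable = [c for c in predicting if c.direction in directions]
            if lead is not None and lead.direction in directions and usable:
                converted = lead.converted_codon
                ref_idx = lead.ref_codon_index
                factor_ids = sorted({i for c in homologous for i in c.factor_ids})
                for p in sorted(lead.required_query_edits):
                    full_after = converted
                    cds_pos = (ref_idx - 1) * 3 + p
                    label = make_label(
                        lead.gene,
                        cds_pos,
                        lead.direction,
                        translate_codon(qcodon, transl_table),
                        translate_codon(full_after, transl_table),
                    )
                    rows.append(
                        CommonsRow(
                            label=label,
                            gene=lead.gene,
                            direction=lead.direction,
                            query_codon_start=qstart,
                            strand=strand,
                            codon_position=p,
                            query_codon_before=qcodon,
                            query_codon_after=full_after,
                            cells=dict(cells),
                            support_percent=round(support, 1),
                            included_by=emit,
                            factor_links=factor_ids,
                        )
                    )

        if stop_removal_prognosis and "N" not in qcodon:
            if translate_codon(qcodon, transl_table) == "*":
                sense = [
                    c
                    for c in sorted(editable_codons(qcodon, Direction.U_TO_C))
                    if translate_codon(c, transl_table) != "*"
                ]
                if sense:
                    pref = [c for c in sense if translate_codon(c, transl_table) in "RQ"]
                    pool = pref or sense
                    pool.sort(key=lambda c: (sum(a != b for a, b in zip(qcodon, c)), c))
                    cand = pool[0]
                    changed = [i + 1 for i, (a, b) in enumerate(zip(qcodon, cand)) if a != b]
                    already = {
                        (r.query_codon_start, r.strand, r.codon_position)
                        for r in rows
                        if r.direction is Direction.U_TO_C
                    }
                    gene = next(
                        (c.gene for c in cells.values() if c.gene), "query"
                    )
                    ref_idx = next(
                        (c.ref_codon_index for c in cells.values() if c.ref_codon_index),
                        (qstart + 2) // 3,
                        )
                    for p in changed:
                        if (qstart, strand, p) in already:
                            continue
                        cds_pos = (ref_idx - 1) * 3 + p
                        rows.append(
                            CommonsRow(
                                label=make_label(
                                    gene, cds_pos, Direction.U_TO_C,
                                    "*", translate_codon(cand, transl_table),
                                ),
                                gene=gene,
                                direction=Direction.U_TO_C,
                                query_codon_start=qstart,
                                strand=strand,
                                codon_position=p,
                                query_codon_before=qcodon,
                                query_codon_after=cand,
                                cells=dict(cells),
                                support_percent=round(support, 1),
                                included_by="stop_removal",
                            )
                        )
    rows.sort(key=lambda r: (r.strand, r.query_codon_start, r.codon_position))
    return rows


# named filter presets; `recheck` flags strongly supported candidate sites
# for re-examination (support >= 80% or at least one edited reference)
PRESETS = {
    "default": dict(threshold_percent=70.0),
    "recheck": dict(threshold_percent=80.0, always_include_reference_sites=True),
}


def predict(
    query: SequenceRecord,
    refs: list[Editome],
    params: SearchParams | None = None,
    directions=BOTH_DIRECTIONS,
    **commons_kwargs,
) -> tuple[list[CommonsRow], list[AlignmentHit]]:
    """Full pipeline: translated search, per-cell prediction, commons table."""
    hits = translated_search(query, refs, params)
    cells_by_codon: dict[tuple[str, int, str], dict[str, PredictionCell]] = {}
    for h in hits:
        table = int(h.protein.transl_table)
        for col in h.columns:
            key = (h.strand, col.query_codon_start, col.query_codon)
            cell = predict_cell(col.query_codon, col, directions, table)
            cell.ref_source = h.ref_source
            cell.gene = h.gene
            cell.align_score = h.score
            cellmap = cells_by_codon.setdefault(key, {})
            if h.ref_source not in cellmap:
                cellmap[h.ref_source] = cell
    # mark references aligned to the gene but gapped at a codon: stay absent
    # (no_homology at that site) per the hyphen rule
    rows = commons(cells_by_codon, directions=directions, **commons_kwargs)
    return rows, hits


# ---------------------------------------------------------------------------
# alignment and cDNA modes


@dataclass
class AlignedRow:
    """One gapped row of a nucleotide multiple alignment."""

    id: str
    seq: str  # may contain '-'

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")


def alignment_mode(
    msa: list[AlignedRow],
    reference_editomes: dict[str, Editome],
    share_threshold: int = 2,
    directions=BOTH_DIRECTIONS,
) -> dict:
    """Map reference edits onto an aligned gene and predict per row.

    ``msa`` is an equal-length gapped nucleotide alignment whose rows are
    in-frame coding sequences of one gene; rows named in
    ``reference_editomes`` are annotated references contributing documented
    edits, all other rows receive predictions at the mapped columns.
    Returns the per-row/per-column matrix, per-column shared counts of
    edited+predicted rows and the columns shaded at ``share_threshold``
    (grey background in graphic displays).
    """
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0].seq)
    for rec in msa:
        if len(rec.seq) != L:
            raise ValueError(f"alignment rows differ in length ({rec.id})")
    ungapped_index = {}
    for rec in msa:
        idx, count = [], 0
        for ch in rec.seq:
            if ch == "-":
                idx.append(None)
            else:
                idx.append(count)
                count += 1
        ungapped_index[rec.id] = idx

    def column_of(rec_id: str, ungapped0: int) -> int | None:
        for col, u in enumerate(ungapped_index[rec_id]):
            if u == ungapped0:
                return col
        return None

    edits_by_column: dict[int, list[tuple[str, AnnotatedEdit]]] = {}
    ref_gene = {}
    for rec in msa:
        if rec.id not in reference_editomes:
            continue
        ed = reference_editomes[rec.id]
        row_seq = rec.seq.replace("-", "").upper().replace("U", "T")
        for e in ed.applied_edits():
            if e.orphan:
                continue
            gene_seq = None
            for cds in ed.cds_features():
                if (cds.gene or "") == e.site.gene:
                    gene_seq = ed.cds_sequence(cds)
                    break
            if gene_seq is None or gene_seq[: len(row_seq)] != row_seq[: len(gene_seq)]:
                # row must be (a prefix of) this gene's CDS to map positions
                if gene_seq is None or row_seq not in gene_seq:
                    continue
            if e.site.cds_pos > len(row_seq):
                continue
            col = column_of(rec.id, e.site.cds_pos - 1)
            if col is not None:
                edits_by_column.setdefault(col, []).append((rec.id, e))
                ref_gene[rec.id] = e.site.gene

    matrix: dict[tuple[str, int], PredictionCell] = {}
    for col, refedits in sorted(edits_by_column.items()):
        for rec in msa:
            if rec.id in reference_editomes:
                continue
            u = ungapped_index[rec.id][col]
            if u is None:
                continue
            row_seq = rec.seq.replace("-", "").upper().replace("U", "T")
            c0 = (u // 3) * 3
            qcodon = row_seq[c0 : c0 + 3]
            if len(qcodon) < 3:
                continue
            ref_id, e = refedits[0]
            ref_codon = RefCodon(
                codon_before=e.site.codon_before,
                codon_after=e.site.codon_after,
                aa_genomic=e.site.aa_before or "X",
                aa_edited=e.site.aa_after or "X",
                edits=[e],
            )
            cell = predict_cell(
                qcodon,
                AlignedColumn(
                    query_codon_start=c0 + 1,
                    query_codon=qcodon,
                    ref_codon_index=e.site.codon_index,
                    ref=ref_codon,
                ),
                directions,
            )
            cell.ref_source = ref_id
            cell.gene = e.site.gene
            matrix[(rec.id, col)] = cell

    shared_counts: dict[int, int] = {}
    for col in edits_by_column:
        n = len({rid for rid, _ in edits_by_column[col]})
        n += sum(
            1
            for (rid, c), cell in matrix.items()
            if c == col and cell.predicting
        )
        shared_counts[col] = n
    shaded = sorted(c for c, n in shared_counts.items() if n >= share_threshold)
    return {
        "matrix": matrix,
        "edits_by_column": edits_by_column,
        "shared_counts": shared_counts,
        "shaded_columns": shaded,
    }


def call_edits_from_cdna(
    genomic_cds: str,
    cdna: str,
    gene: str,
    transl_table: int = 1,
) -> tuple[list[EditingSite], list[tuple[int, str, str]]]:
    """Call editing events from a genomic CDS / cDNA pair.

    Sequences must be pre-aligned (equal length; gap columns allowed and
    skipped).  Every genomic C read as T in the cDNA is a C-to-U event and
    every genomic T read as C a U-to-C event; any other mismatch is returned
    separately as (cds_pos, genomic, cdna) and never called an edit.
    """
    g = genomic_cds.upper().replace("U", "T")
    c = cdna.upper().replace("U", "T")
    if len(g) != len(c):
        raise ValueError(
            f"genomic and cDNA sequences differ in length ({len(g)} vs {len(c)}); "
            "align them first"
        )
    pairs = [(a, b) for a, b in zip(g, c) if not (a == "-" or b == "-")]
    g = "".join(a for a, _ in pairs)
    c = "".join(b for _, b in pairs)
    edited_positions: dict[int, Direction] = {}
    mismatches: list[tuple[int, str, str]] = []
    for i, (a, b) in enumerate(zip(g, c), start=1):
        if a == b:
            continue
        if (a, b) == ("C", "T"):
            edited_positions[i] = Direction.C_TO_U
        elif (a, b) == ("T", "C"):
            edited_positions[i] = Direction.U_TO_C
        else:
            mismatches.append((i, a, b))
    sites = []
    for pos, d in sorted(edited_positions.items()):
        c0 = ((pos - 1) // 3) * 3
        codon_before = g[c0 : c0 + 3]
        if len(codon_before) < 3:
            codon_before = codon_before.ljust(3, "N")
        after = list(codon_before)
        for p, dd in edited_positions.items():
            if c0 < p <= c0 + 3 and p - 1 - c0 < len(after):
                after[p - 1 - c0] = dd.edited_base
        sites.append(
            EditingSite(
                gene=gene,
                cds_pos=pos,
                direction=d,
                codon_before=codon_before,
                codon_after="".join(after),
                transl_table=transl_table,
            )
        )
    return sites, mismatches


# ---------------------------------------------------------------------------
# output helpers


def cell_display(cell: PredictionCell) -> str:
    """Commons-table cell encoding: RED = supported by a documented edit in
    the reference, BLACK = pre-edited reference codon, a bare amino acid for
    non-contributing references, '-' only for lacking homology."""
    if cell.status == "edited_in_ref":
        return f"RED:{cell.ref_aa}"
    if cell.status == "pre_edited_in_ref":
        return f"BLACK:{cell.ref_aa}"
    if cell.status == "no_homology":
        return "-"
    return cell.ref_aa


def commons_to_frame(rows: list[CommonsRow], ref_ids: list[str] | None = None) -> pd.DataFrame:
    if ref_ids is None:
        seen: list[str] = []
        for r in rows:
            for rid in r.cells:
                if rid not in seen:
                    seen.append(rid)
        ref_ids = seen
    out = []
    for r in rows:
        rec = {
            "label": r.label,
            "gene": r.gene,
            "direction": r.direction.value,
            "strand": r.strand,
            "query_codon_start": r.query_codon_start,
            "codon_position": r.codon_position,
            "codon_before": r.query_codon_before,
            "codon_after": r.query_codon_after,
            "support_percent": r.support_percent,
            "included_by": r.included_by,
            "known_factor": bool(r.factor_links),
            "factor_links": ";".join(f"EdiFacts:{i}" for i in r.factor_links),
        }
        for rid in ref_ids:
            cell = r.cells.get(rid)
            rec[rid] = cell_display(cell) if cell else "-"
        out.append(rec)
    return pd.DataFrame(out)


def commons_to_html(rows: list[CommonsRow], ref_ids: list[str] | None = None) -> str:
    """Static HTML rendering of the commons table.  CSS classes carry the
    display semantics: ``red`` for predictions via a documented reference
    edit, ``black`` for pre-edited references, plain amino acids for
    non-contributing references, a hyphen for lacking homology, and
    ``factor`` (italic + underline) for sites with a characterized factor."""
    frame = commons_to_frame(rows, ref_ids)
    css = ("<style>td.red{color:#c00;font-weight:bold}td.black{color:#000;"
           "font-weight:bold}td.factor{font-style:italic;text-decoration:"
           "underline}table{border-collapse:collapse}td,th{border:1px solid "
           "#999;padding:2px 6px}</style>")
    ref_cols = [c for c in frame.columns if c not in {
        "label", "gene", "direction", "strand", "query_codon_start",
        "codon_position", "codon_before", "codon_after", "support_percent",
        "included_by", "known_factor", "factor_links"}]
    head = "".join(f"<th>{h}</th>" for h in ["site", "support %", *ref_cols])
    body = []
    for _, row in frame.iterrows():
        label_cls = "factor" if row["known_factor"] else ""
        cells = [f'<td class="{label_cls}">{row["label"]}</td>',
                 f"<td>{row['support_percent']}</td>"]
        for rid in ref_cols:
            val = row[rid]
            if val.startswith("RED:"):
                cells.append(f'<td class="red">{val[4:]}</td>')
            elif val.startswith("BLACK:"):
                cells.append(f'<td class="black">{val[6:]}</td>')
            else:
                cells.append(f"<td>{val}</td>")
        body.append(f"<tr>{''.join(cells)}</tr>")
    return f"{css}<table><tr>{head}</tr>{''.join(body)}</table>"


def annotate_query(
    query: SequenceRecord, rows: list[CommonsRow], species: str = "", organelle: str = ""
) -> Editome:
    """Write predicted sites back onto the query as RNA_editing features
    with ``/applied="no"``."""
    n = len(query.seq)
    feats = []
    for r in rows:
        sense0 = (r.query_codon_start - 1) + (r.codon_position - 1)
        if r.strand == "+":
            gpos = sense0 + 1
        else:
            gpos = n - sense0
        feats.append(
            Feature(
                kind="RNA_editing",
                record_id=query.id,
                location=[Interval(gpos, gpos, r.strand)],
                qualifiers={
                    "direction": [r.direction.value],
                    "label": [r.label],
                    "applied": ["no"],
                    "note": [f"predicted, support {r.support_percent}%"],
                },
            )
        )
    return Editome(records=[SequenceRecord(query.id, query.seq)], features=feats,
                   species=species, organelle=organelle)
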
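"""Position-weighted motif definition and scanning.

A scan matrix is an ordered list of columns; each column assigns every base
an integer percentage (summing to 100) plus an overall integer position
weight.  The score of a window is the sum over columns of
``base_value x weight / 100``; a column weighted 0 never contributes.  One
column may be flagged as the *anchor* (the candidate edited cytidine): in
edit-anchored scans the anchor is placed over the documented edit, and an
optional flat bonus is added whenever the base under the anchor is C.

Scores are computed exactly in integer hundredths (``value x weight`` is an
integer) and reported as integers whenever exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from editomics.editome_io import Editome, Feature, Interval, SequenceRecord
from editomics.nomenclature import Direction

__all__ = [
    "BASES",
    "WeightColumn",
    "WeightMatrix",
    "ScanHit",
    "normalize_column",
    "score_window",
    "scan",
    "max_score",
    "colour_code",
    "matrix_to_tsv",
    "matrix_from_tsv",
]

BASES = ("A", "C", "G", "T")


def _as_score(hundredths: int) -> int | float:
    return hundredths // 100 if hundredths % 100 == 0 else hundredths / 100


@dataclass
class WeightColumn:
    """One matrix position: base percentages (sum 100) and a position weight."""

    values: dict[str, int]
    weight: int = 100
    locked: frozenset[str] = frozenset()
    is_anchor: bool = False

    def __post_init__(self) -> None:
        self.values = {b: int(self.values.get(b, 0)) for b in BASES}
        if sum(self.values.values()) != 100:
            raise ValueError(f"column values must sum to 100, got {self.values}")
        if self.weight < 0:
            raise ValueError("column weight must be >= 0")
        self.locked = frozenset(self.locked)

    def score_hundredths(self, base: str) -> int:
        """value x weight for one base, in integer hundredths of a score unit.

        ``N`` (or any non-ACGT character) scores 0.
        """
        return self.values.get(base, 0) * self.weight

    @property
    def max_hundredths(self) -> int:
        return max(self.values.values()) * self.weight

    @property
    def min_hundredths(self) -> int:
        return min(self.values.values()) * self.weight


def normalize_column(
    locked_values: dict[str, int],
    weight: int = 100,
    is_anchor: bool = False,
) -> WeightColumn:
    """Build a column from locked base values, distributing the remainder.

    The non-locked bases share ``100 - sum(locked)`` evenly; any remainder of
    the integer division is assigned deterministically in base order
    A, C, G, T.  Locking A=15, C=35, G=5 therefore auto-assigns T=45; locking
    nothing yields the non-selective 25/25/25/25 column.
    """
    locked = {b: int(v) for b, v in locked_values.items()}
    unknown = set(locked) - set(BASES)
    if unknown:
        raise ValueError(f"unknown bases {sorted(unknown)}")
    total = sum(locked.values())
    if total > 100:
        raise ValueError(f"locked values sum to {total} > 100")
    free = [b for b in BASES if b not in locked]
    values = dict(locked)
    if free:
        share, rem = divmod(100 - total, len(free))
        for i, b in enumerate(free):
            values[b] = share + (1 if i < rem else 0)
    elif total != 100:
        raise ValueError("all bases locked but values do not sum to 100")
    return WeightColumn(values=values, weight=weight,
                        locked=frozenset(locked), is_anchor=is_anchor)


@dataclass
class WeightMatrix:
    """Ordered list of weight columns."""

    columns: list[WeightColumn]
    name: str = "matrix"

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("matrix must have at least one column")
        if sum(c.is_anchor for c in self.columns) > 1:
            raise ValueError("at most one anchor column per matrix")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def anchor_index(self) -> int | None:
        for i, c in enumerate(self.columns):
            if c.is_anchor:
                return i
        return None


def score_window(window: str, matrix: WeightMatrix) -> tuple[int | float, list[int | float]]:
    """Score one window: per-column ``value x weight / 100`` plus their sum."""
    window = window.upper().replace("U", "T")
    if len(window) != len(matrix):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(matrix)}"
        )
    per_h = [col.score_hundredths(b) for b, col in zip(window, matrix.columns)]
    return _as_score(sum(per_h)), [_as_score(h) for h in per_h]


def max_score(matrix: WeightMatrix, edit_bonus: int | float = 0) -> int | float:
    """Maximum attainable total; the anchor bonus counts when present."""
    total_h = sum(c.max_hundredths for c in matrix.columns)
    bonus_h = round(edit_bonus * 100) if matrix.anchor_index is not None else 0
    return _as_score(total_h + bonus_h)


@dataclass
class ScanHit:
    """A scored window from a scan."""

    source_id: str
    start: int  # 1-based, + strand coordinate of the window's first base
    strand: str
    window: str
    per_column: list[int | float]
    total: int | float
    context: list[str] = field(default_factory=list)
    edited_positions: list[int] = field(default_factory=list)  # window offsets (0-based) over documented edits
    bonus_applied: bool = False
    rank: int = 0

    @property
    def sort_key(self):
        return (-(self.total), self.source_id, self.strand, self.start)


def _window_at(seq: str, start0: int, length: int, circular: bool) -> str | None:
    n = len(seq)
    if start0 + length <= n:
        return seq[start0 : start0 + length]
    if circular:
        return (seq + seq)[start0 : start0 + length]
    return None


def _feature_context(editome: Editome | None, record_id: str,
                     start: int, end: int) -> list[str]:
    names = []
    if editome is None:
        return names
    for f in editome.features:
        if f.kind not in ("gene", "CDS") or f.record_id != record_id:
            continue
        for iv in f.location:
            if iv.ref is None and iv.start <= end and start <= iv.end:
                name = f.gene or f.kind
                if name not in names:
                    names.append(name)
    return names


def _rank_and_cut(hits: list[ScanHit], top_n: int | None, include_ties: bool) -> list[ScanHit]:
    hits.sort(key=lambda h: h.sort_key)
    if top_n is not None and len(hits) > top_n:
        if include_ties:
            cutoff = hits[top_n - 1].total
            hits = [h for h in hits if h.total >= cutoff]
        else:
            hits = hits[:top_n]
    for i, h in enumerate(hits, start=1):
        h.rank = i
    return hits


def scan(
    sources: list[Editome] | list[SequenceRecord],
    matrix: WeightMatrix,
    mode: str = "genome",
    direction: Direction | None = None,
    top_n: int | None = None,
    include_ties: bool = True,
    edit_bonus: int | float = 0,
    strand: str = "both",
) -> list[ScanHit]:
    """Slide the matrix over the sources and return ranked hits.

    mode
        ``genome`` slides over every position of every record (both strands
        by default); ``cds`` slides over each spliced CDS in sense
        orientation; ``edit_anchored`` evaluates exactly one window per
        documented edit, with the anchor column over the edited base
        (requires annotated sources and an anchor column).
    direction
        in edit-anchored mode, restrict to edits of this direction.
    edit_bonus
        flat bonus added to the total when the base under the anchor column
        is C (candidate cytidine targets); requires an anchor column.
    top_n / include_ties
        ranking is by descending total; with ``include_ties`` all hits
        scoring equal to the ``top_n``-th hit are also returned, avoiding an
        arbitrary cut among equally good matches.

    Ties within equal totals break deterministically by
    (source id, strand, start) ascending.
    """
    if mode not in ("genome", "cds", "edit_anchored"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if edit_bonus and matrix.anchor_index is None:
        raise ValueError("edit_bonus requires a matrix with an anchor column")

    editomes: list[Editome] = []
    for src in sources:
        if isinstance(src, Editome):
            editomes.append(src)
        else:
            editomes.append(Editome(records=[src]))

    L = len(matrix)
    hits: list[ScanHit] = []

    if mode == "genome":
        strands = ("+", "-") if strand == "both" else (strand,)
        for ed in editomes:
            for rec in ed.records:
                circular = rec.topology == "circular"
                n = len(rec.seq)
                n_windows = n if circular else n - L + 1
                for st in strands:
                    seq = rec.seq if st == "+" else str(Seq(rec.seq).reverse_complement())
                    for i in range(max(n_windows, 0)):
                        win = _window_at(seq, i, L, circular)
                        if win is None:
                            continue
                        total, per = score_window(win, matrix)
                        bonus = False
                        ai = matrix.anchor_index
                        if edit_bonus and ai is not None and win[ai] == "C":
                            total = _as_score(round(total * 100) + round(edit_bonus * 100))
                            bonus = True
                        # report window start in + strand coordinates
                        if st == "+":
                            start = i + 1
                        else:
                            start = n - ((i + L - 1) % n) if circular else n - (i + L) + 1
                        hits.append(
                            ScanHit(
                                source_id=rec.id, start=start, strand=st,
                                window=win, per_column=per, total=total,
                                context=_feature_context(ed, rec.id, start, start + L - 1),
                                bonus_applied=bonus,
                            )
                        )
        return _rank_and_cut(hits, top_n, include_ties)

    if mode == "cds":
        for ed in editomes:
            for cds in ed.cds_features():
                if any(iv.ref and iv.ref.split(".")[0] not in
                       {r.id.split(".")[0] for r in ed.records} for iv in cds.location):
                    continue
                seq = ed.cds_sequence(cds)
                gene = cds.gene or cds.record_id
                edited0 = {
                    e.site.cds_pos - 1
                    for e in ed.applied_edits()
                    if e.feature is not None and e.site.gene == gene
                }
                for i in range(len(seq) - L + 1):
                    win = seq[i : i + L]
                    total, per = score_window(win, matrix)
                    bonus = False
                    ai = matrix.anchor_index
                    if edit_bonus and ai is not None and win[ai] == "C":
                        total = _as_score(round(total * 100) + round(edit_bonus * 100))
                        bonus = True
                    hits.append(
                        ScanHit(
                            source_id=f"{ed.id}|{gene}", start=i + 1, strand="+",
                            window=win, per_column=per, total=total,
                            context=[gene],
                            edited_positions=[p - i for p in edited0 if i <= p < i + L],
                            bonus_applied=bonus,
                        )
                    )
        return _rank_and_cut(hits, top_n, include_ties)

    # edit_anchored
    ai = matrix.anchor_index
    if ai is None:
        raise ValueError("edit_anchored mode requires a matrix with an anchor column")
    for ed in editomes:
        if not ed.edits:
            raise ValueError(
                f"edit_anchored mode needs annotated sources; {ed.id} has no edits"
            )
        cds_seq_cache: dict[int, str] = {}
        for e in ed.applied_edits(direction):
            if e.feature is None:
                continue
            # window in CDS sense orientation, anchor over the edited base
            host = None
            for cds in ed.cds_features():
                p = ed.cds_position_of(cds, e.record_id, e.genome_pos)
                if p == e.site.cds_pos and (cds.gene or cds.record_id) == e.site.gene:
                    host = cds
                    break
            if host is None:
                continue
            if id(host) not in cds_seq_cache:
                cds_seq_cache[id(host)] = ed.cds_sequence(host)
            seq = cds_seq_cache[id(host)]
            codon_start = int(host.qualifier("codon_start", "1"))
            spliced0 = e.site.cds_pos - 1 + (codon_start - 1)
            start0 = spliced0 - ai
            if start0 < 0 or start0 + L > len(seq):
                continue  # window truncated at the CDS boundary
            win = seq[start0 : start0 + L]
            total, per = score_window(win, matrix)
            bonus = False
            if edit_bonus and win[ai] == "C":
                total = _as_score(round(total * 100) + round(edit_bonus * 100))
                bonus = True
            hits.append(
                ScanHit(
                    source_id=f"{ed.id}|{e.site.label}", start=start0 + 1,
                    strand=e.strand, window=win, per_column=per, total=total,
                    context=[e.site.gene], edited_positions=[ai],
                    bonus_applied=bonus,
                )
            )
    return _rank_and_cut(hits, top_n, include_ties)


_COLOUR_BUCKETS = ("red", "orange", "yellow", "lightgreen", "green")


def colour_code(hit: ScanHit, matrix: WeightMatrix) -> list[str | None]:
    """Per-column colour category from green (column maximum = perfect match)
    to red (column minimum); zero-weight columns are excluded (None)."""
    cats: list[str | None] = []
    for base, col in zip(hit.window, matrix.columns):
        if col.weight == 0:
            cats.append(None)
            continue
        lo, hi = col.min_hundredths, col.max_hundredths
        v = col.score_hundredths(base)
        if hi == lo:
            cats.append("green")
            continue
        frac = (v - lo) / (hi - lo)
        idx = min(int(frac * len(_COLOUR_BUCKETS)), len(_COLOUR_BUCKETS) - 1)
        cats.append(_COLOUR_BUCKETS[idx])
    return cats


# ---------------------------------------------------------------------------
# matrix TSV round-trip


def matrix_to_tsv(matrix: WeightMatrix) -> str:
    """Serialise a matrix as TSV: ``pos A C G T weight anchor``."""
    lines = ["pos\tA\tC\tG\tT\tweight\tanchor"]
    for i, col in enumerate(matrix.columns, start=1):
        lines.append(
            "\t".join(
                [str(i)]
                + [str(col.values[b]) for b in BASES]
                + [str(col.weight), "1" if col.is_anchor else "0"]
            )
        )
    return "\n".join(lines) + "\n"


def matrix_from_tsv(text: str, name: str = "matrix") -> WeightMatrix:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[:7] != ["pos", "A", "C", "G", "T", "weight", "anchor"]:
        raise ValueError(f"bad matrix header: {lines[0]!r}")
    cols = []
    for ln in lines[1:]:
        f = ln.split("\t")
        cols.append(
            WeightColumn(
                values={b: int(v) for b, v in zip(BASES, f[1:5])},
                weight=int(f[5]),
                is_anchor=f[6] == "1",
            )
        )
    return WeightMatrix(columns=cols, name=name)


def search_features_for_scan(
    editome: Editome, hits: list[ScanHit], matrix: WeightMatrix, mode: str
) -> Editome:
    """Annotate scanned ranges and hits as Search_range / Search_result
    features on a copy of the editome (genome-mode hits only)."""
    import copy

    out = copy.deepcopy(editome)
    for rec in out.records:
        out.features.append(
            Feature(
                kind="Search_range",
                record_id=rec.id,
                location=[Interval(1, len(rec.seq))],
                qualifiers={"note": [f"scan mode {mode}, matrix {matrix.name}"]},
            )
        )
    rec_ids = {r.id for r in out.records}
    for h in hits:
        if h.source_id not in rec_ids:
            continue
        out.features.append(
            Feature(
                kind="Search_result",
                record_id=h.source_id,
                location=[Interval(h.start, h.start + len(matrix) - 1, h.strand)],
                qualifiers={"score": [str(h.total)], "rank": [str(h.rank)]},
            )
        )
    return out
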
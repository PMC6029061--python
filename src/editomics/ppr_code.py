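"""PPR-RNA recognition code: from an annotated PLS repeat array to a scan matrix.

PLS-type pentatricopeptide-repeat (PPR) editing factors bind their RNA target
one nucleotide per repeat.  The empirical recognition code reads two amino
acids per repeat: position 5 distinguishes purines (T or S) from pyrimidines
(N), and position L ("Last") distinguishes keto bases G/U (D) from amino
bases A/C (N).  The canonical combinations are therefore

    T/S + N -> A        T/S + D -> G        N + N/S -> C        N + D -> U

The code applies to P- and S-type repeats only; L-type repeats, the divergent
terminal S2 repeat and non-canonical residue combinations get a neutral,
zero-weight column.  Purine selection is sharper than pyrimidine selection,
which the default parameters express as a 90/10 split at double weight (200)
for purines versus a 70/30 split at weight 100 for pyrimidines.  The position
immediately 5' of the edited cytidine (-1) is not read by a repeat; it gets
an empirical pyrimidine-biased profile (A 15, C 35, G 5, T 45) at weight 100.

Repeats are numbered in reverse: repeat 1 is the last (most C-terminal)
repeat, adjacent to the E1 domain, which sits closest to the edited site.
By default the last repeat aligns to target position -2 and counting
proceeds 5'-wards one nucleotide per repeat; the register is configurable
since the repeat-to-nucleotide alignment is an empirical convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from editomics.targetscan import BASES, WeightColumn, WeightMatrix, normalize_column

__all__ = [
    "PPRMotif",
    "CodeParams",
    "motif_preferences",
    "array_to_matrix",
    "array_from_tsv",
    "array_to_tsv",
]

_MOTIF_TYPES = {"P", "L", "S", "S2"}


@dataclass(frozen=True)
class PPRMotif:
    """One PPR repeat: reverse index (1 = last repeat), type and the two
    code-relevant amino acids."""

    reverse_index: int
    motif_type: str
    aa5: str
    aaL: str

    def __post_init__(self) -> None:
        if self.motif_type not in _MOTIF_TYPES:
            raise ValueError(f"unknown motif type {self.motif_type!r}")
        if self.reverse_index < 1:
            raise ValueError("reverse_index is 1-based")


@dataclass
class CodeParams:
    """Tunable weighting of the recognition code."""

    purine_split: tuple[int, int] = (90, 10)
    pyrimidine_split: tuple[int, int] = (70, 30)
    purine_weight: int = 200
    pyrimidine_weight: int = 100
    minus1_profile: dict[str, int] = field(
        default_factory=lambda: {"A": 15, "C": 35, "G": 5, "T": 45}
    )
    minus1_weight: int = 100
    noncanonical_weight: int = 0

    def __post_init__(self) -> None:
        if sum(self.purine_split) != 100 or sum(self.pyrimidine_split) != 100:
            raise ValueError("splits must sum to 100")
        if sum(self.minus1_profile.get(b, 0) for b in BASES) != 100:
            raise ValueError("-1 profile must sum to 100")


def _split_column(preferred: str, other: str, split: tuple[int, int], weight: int) -> WeightColumn:
    values = {b: 0 for b in BASES}
    values[preferred], values[other] = split
    return WeightColumn(values=values, weight=weight)


def motif_preferences(m: PPRMotif, params: CodeParams | None = None) -> WeightColumn:
    """Weight column for one repeat under the recognition code.

    Canonical P/S repeats yield a selective column; L-type, S2 and any
    non-canonical amino-acid combination yield a neutral 25/25/25/25 column
    at ``noncanonical_weight`` (default 0, i.e. ignored in scoring).
    """
    p = params or CodeParams()
    aa5, aaL = m.aa5.upper(), m.aaL.upper()
    if m.motif_type in ("P", "S"):
        if aa5 in ("T", "S"):  # purine-selecting
            if aaL == "N":
                return _split_column("A", "G", p.purine_split, p.purine_weight)
            if aaL == "D":
                return _split_column("G", "A", p.purine_split, p.purine_weight)
        elif aa5 == "N":  # pyrimidine-selecting
            if aaL in ("N", "S"):
                return _split_column("C", "T", p.pyrimidine_split, p.pyrimidine_weight)
            if aaL == "D":
                return _split_column("T", "C", p.pyrimidine_split, p.pyrimidine_weight)
    return WeightColumn(values={b: 25 for b in BASES}, weight=p.noncanonical_weight)


def array_to_matrix(
    array: list[PPRMotif],
    params: CodeParams | None = None,
    append_minus1: bool = True,
    anchor_bonus: bool = True,
    register_offset: int = 0,
    name: str = "ppr_array",
) -> WeightMatrix:
    """Build a scan matrix from a PPR array.

    The array is laid out 5'->3' along the target RNA, i.e. by descending
    reverse index; the last repeat's column ends immediately 5' of the -1
    position.  ``append_minus1`` adds the empirical -1 profile column;
    ``anchor_bonus`` appends the anchor column over the candidate edited C
    (neutral values, weight 0 — it contributes only the optional edit
    bonus in anchored scans).  ``register_offset`` shifts the repeat block
    by inserting (positive) or dropping (negative) neutral columns between
    the repeats and the -1 column.
    """
    if not array:
        raise ValueError("empty PPR array")
    p = params or CodeParams()
    ordered = sorted(array, key=lambda m: -m.reverse_index)
    columns = [motif_preferences(m, p) for m in ordered]
    if register_offset > 0:
        columns += [
            WeightColumn(values={b: 25 for b in BASES}, weight=0)
            for _ in range(register_offset)
        ]
    elif register_offset < 0:
        columns = columns[:register_offset]
        if not columns:
            raise ValueError("register_offset removes every repeat column")
    if append_minus1:
        columns.append(WeightColumn(values=dict(p.minus1_profile), weight=p.minus1_weight))
    if anchor_bonus:
        columns.append(
            WeightColumn(values={b: 25 for b in BASES}, weight=0, is_anchor=True)
        )
    return WeightMatrix(columns=columns, name=name)


# ---------------------------------------------------------------------------
# PPR array TSV: "reverse_index<TAB>type<TAB>aa5<TAB>aaL", one repeat per row


def array_from_tsv(text: str) -> list[PPRMotif]:
    motifs = []
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    start = 1 if lines and lines[0].lower().startswith("reverse_index") else 0
    for ln in lines[start:]:
        f = ln.split("\t")
        if len(f) != 4:
            raise ValueError(f"bad PPR array row: {ln!r}")
        motifs.append(PPRMotif(int(f[0]), f[1], f[2], f[3]))
    seen = [m.reverse_index for m in motifs]
    if len(seen) != len(set(seen)):
        raise ValueError("duplicate reverse_index in PPR array")
    return motifs


def array_to_tsv(array: list[PPRMotif]) -> str:
    lines = ["reverse_index\ttype\taa5\taaL"]
    for m in sorted(array, key=lambda m: -m.reverse_index):
        lines.append(f"{m.reverse_index}\t{m.motif_type}\t{m.aa5}\t{m.aaL}")
    return "\n".join(lines) + "\n"
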
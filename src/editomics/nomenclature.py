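"""Canonical editing-site labels, codon arithmetic and edit classification.

A plant-organelle editing event is labelled by the affected gene, the letter
``e`` for editing, the nucleotide *introduced* by the edit (``U`` for C-to-U,
``C`` for U-to-C), the 1-based nucleotide position in the coding sequence,
and the amino acids encoded before and after editing, e.g. ``atp9eU92SL``:
a C-to-U edit at coding position 92 of *atp9* turning a serine codon into a
leucine codon.  Stop codons are rendered as ``X`` in labels (configurable);
silent edits repeat the amino acid (``...eU276SS``).  For edits outside any
CDS a gene + genome-position fallback label without the amino-acid pair is
used.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "Direction",
    "EditingSite",
    "make_label",
    "parse_label",
    "codon_coords",
    "classify_edit",
    "translate_codon",
    "LabelError",
]


class LabelError(ValueError):
    """Raised when an editing-site label cannot be parsed or built."""


class Direction(str, enum.Enum):
    """Direction of a pyrimidine-exchange editing event."""

    C_TO_U = "C_to_U"
    U_TO_C = "U_to_C"

    @property
    def introduced(self) -> str:
        """Nucleotide letter introduced by editing, as printed in labels."""
        return "U" if self is Direction.C_TO_U else "C"

    @property
    def genomic_base(self) -> str:
        """Base present in the genome (DNA alphabet) before editing."""
        return "C" if self is Direction.C_TO_U else "T"

    @property
    def edited_base(self) -> str:
        """Base present in the transcript (DNA alphabet) after editing."""
        return "T" if self is Direction.C_TO_U else "C"

    @classmethod
    def from_introduced(cls, letter: str) -> "Direction":
        if letter == "U":
            return cls.C_TO_U
        if letter == "C":
            return cls.U_TO_C
        raise LabelError(f"introduced nucleotide must be U or C, got {letter!r}")


# Amino-acid letters accepted in labels. '*' is the internal stop; STOP_CHAR
# is what labels display for it.
STOP_CHAR = "X"
_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"*", STOP_CHAR}

_LABEL_RE = re.compile(r"^(?P<gene>.+)e(?P<intro>[UC])(?P<pos>\d+)(?:(?P<aa1>[A-Z*])(?P<aa2>[A-Z*]))?$")


def translate_codon(codon: str, transl_table: int = 1) -> str:
    """Translate one codon to a single-letter amino acid ('*' for stop)."""
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return str(Seq(codon).translate(table=transl_table))


def codon_coords(cds_pos: int) -> tuple[int, int]:
    """Map a 1-based CDS nucleotide position to (codon_index, codon_position).

    ``codon_index`` is 1-based (= ceil(cds_pos/3)); ``codon_position`` is
    1, 2 or 3 within the codon.

    >>> codon_coords(92)
    (31, 2)
    """
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3), ((cds_pos - 1) % 3) + 1


def make_label(
    gene: str,
    cds_pos: int,
    direction: Direction,
    aa_before: str | None = None,
    aa_after: str | None = None,
    stop_char: str = STOP_CHAR,
) -> str:
    """Build the canonical label for an editing site.

    The amino-acid pair is omitted only when the site lies outside any CDS
    (both ``aa_before`` and ``aa_after`` are None).
    """
    if cds_pos < 1:
        raise LabelError(f"cds_pos must be >= 1, got {cds_pos}")
    direction = Direction(direction)
    core = f"{gene}e{direction.introduced}{cds_pos}"
    if aa_before is None and aa_after is None:
        return core
    if aa_before is None or aa_after is None:
        raise LabelError("aa_before and aa_after must both be given or both omitted")
    pair = ""
    for aa in (aa_before, aa_after):
        if aa not in _AA_LETTERS:
            raise LabelError(f"invalid amino-acid letter {aa!r}")
        pair += stop_char if aa == "*" else aa
    return core + pair


def parse_label(label: str, stop_char: str = STOP_CHAR) -> tuple[str, int, Direction, str | None, str | None]:
    """Parse a label back into (gene, cds_pos, direction, aa_before, aa_after).

    Inverse of :func:`make_label`; the gene name is matched greedily so gene
    names containing upper-case letters (``ccmFC``) parse correctly.
    """
    m = _LABEL_RE.match(label)
    if not m:
        raise LabelError(f"label {label!r} does not match the nomenclature grammar")
    gene = m.group("gene")
    direction = Direction.from_introduced(m.group("intro"))
    cds_pos = int(m.group("pos"))
    if cds_pos < 1:
        raise LabelError(f"label {label!r} has cds position < 1")
    aa1, aa2 = m.group("aa1"), m.group("aa2")
    if aa1 is not None:
        aa1 = "*" if aa1 == stop_char else aa1
        aa2 = "*" if aa2 == stop_char else aa2
        for aa in (aa1, aa2):
            if aa not in _AA_LETTERS:
                raise LabelError(f"invalid amino-acid letter {aa!r} in {label!r}")
    return gene, cds_pos, direction, aa1, aa2


# Leucine codons with a synonymous first-position C<->U exchange (YUR codons:
# UUA/UUG <-> CUA/CUG), written in DNA alphabet.
YUR_LEUCINE_CODONS = {"TTA", "TTG", "CTA", "CTG"}


@dataclass
class EditClassification:
    """Joint classification of the codon change caused by editing."""

    codon_positions_changed: set[int]
    silent: bool
    stop_removed: bool
    stop_introduced: bool
    aa_before: str
    aa_after: str
    yur_leucine: bool = False

    @property
    def missense(self) -> bool:
        return not self.silent and not self.stop_removed and not self.stop_introduced


def classify_edit(
    codon_before: str,
    codon_after: str,
    direction: Direction,
    transl_table: int = 1,
) -> EditClassification:
    """Classify the codon change of one (possibly multi-nucleotide) edit.

    Both codons are compared position-wise; every differing position must be
    a C->T (C_to_U) or T->C (U_to_C) exchange consistent with ``direction``.
    Silent changes include third-position synonymous exchanges and the
    first-position leucine YUR codons.
    """
    direction = Direction(direction)
    before = codon_before.upper().replace("U", "T")
    after = codon_after.upper().replace("U", "T")
    if len(before) != 3 or len(after) != 3:
        raise ValueError("codons must have length 3")
    changed: set[int] = set()
    for i, (b, a) in enumerate(zip(before, after), start=1):
        if b == a:
            continue
        if (b, a) != (direction.genomic_base, direction.edited_base):
            raise ValueError(
                f"codon change {before}->{after} at position {i} is not a "
                f"{direction.value} exchange"
            )
        changed.add(i)
    aa_before = translate_codon(before, transl_table)
    aa_after = translate_codon(after, transl_table)
    silent = aa_before == aa_after and bool(changed)
    yur = silent and changed == {1} and before in YUR_LEUCINE_CODONS
    return EditClassification(
        codon_positions_changed=changed,
        silent=silent,
        stop_removed=aa_before == "*" and aa_after != "*",
        stop_introduced=aa_before != "*" and aa_after == "*",
        aa_before=aa_before,
        aa_after=aa_after,
        yur_leucine=yur,
    )


@dataclass
class EditingSite:
    """One C<->U editing event located in a coding sequence.

    ``cds_pos`` is the 1-based nucleotide position within the spliced coding
    sequence in sense orientation.  ``codon_before``/``codon_after`` hold the
    affected codon before and after editing; for codons edited at more than
    one position, ``codon_after`` is the fully edited codon while each edited
    nucleotide carries its own :class:`EditingSite`.
    """

    gene: str
    cds_pos: int
    direction: Direction
    codon_before: str = ""
    codon_after: str = ""
    aa_before: str | None = None
    aa_after: str | None = None
    applied: bool = True
    db_xrefs: list[int] = field(default_factory=list)
    transl_table: int = 1

    def __post_init__(self) -> None:
        self.direction = Direction(self.direction)
        self.codon_before = self.codon_before.upper().replace("U", "T")
        self.codon_after = self.codon_after.upper().replace("U", "T")
        if self.codon_before and self.aa_before is None:
            self.aa_before = translate_codon(self.codon_before, self.transl_table)
        if self.codon_after and self.aa_after is None:
            self.aa_after = translate_codon(self.codon_after, self.transl_table)

    @property
    def codon_index(self) -> int:
        return codon_coords(self.cds_pos)[0]

    @property
    def codon_position(self) -> int:
        return codon_coords(self.cds_pos)[1]

    @property
    def label(self) -> str:
        return make_label(self.gene, self.cds_pos, self.direction, self.aa_before, self.aa_after)

    def classification(self) -> EditClassification:
        return classify_edit(self.codon_before, self.codon_after, self.direction, self.transl_table)

    @classmethod
    def from_label(cls, label: str, applied: bool = True) -> "EditingSite":
        gene, cds_pos, direction, aa1, aa2 = parse_label(label)
        return cls(gene=gene, cds_pos=cds_pos, direction=direction,
                   aa_before=aa1, aa_after=aa2, applied=applied)
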
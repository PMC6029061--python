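"""GenBank-style editome I/O.

A reference *editome* is an annotated organelle genome whose CDS-located
editing events are carried as per-nucleotide ``RNA_editing`` features.  This
module reads and writes such records (via Biopython's GenBank machinery),
resolves spliced/remote/partial CDS locations, maps every editing feature to
its CDS-relative coordinate, and assembles multi-chromosome genomes split
across several accessions.

RNA_editing feature dialect used by this package
------------------------------------------------
location
    the single edited nucleotide on the genome (on the CDS strand)
qualifiers
    ``/direction="C_to_U"|"U_to_C"`` (inferred from the genomic base when
    absent), ``/label="<nomenclature label>"``, ``/applied="yes"|"no"``
    (default yes) and optionally ``/db_xref="EdiFacts:<id>"``.  Unknown
    qualifiers are preserved verbatim.

All sequence is stored as DNA (T, never U).  Coordinates are 1-based
inclusive externally, matching GenBank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from editomics.nomenclature import Direction, EditingSite, codon_coords

__all__ = [
    "SequenceRecord",
    "Feature",
    "Interval",
    "AnnotatedEdit",
    "Editome",
    "GenBankParseError",
    "UnresolvedRemoteError",
    "parse_genbank",
    "write_genbank",
    "assemble_multichromosome",
    "read_fasta",
    "write_fasta",
]

_ALPHABET = set("ACGTN")


class GenBankParseError(ValueError):
    pass


class UnresolvedRemoteError(ValueError):
    def __init__(self, accessions: list[str]):
        self.accessions = sorted(set(accessions))
        super().__init__(
            "remote location references unresolved accession(s): "
            + ", ".join(self.accessions)
        )


@dataclass
class SequenceRecord:
    """One nucleotide sequence entry (chromosome / accession)."""

    id: str
    seq: str
    topology: str = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(f"record {self.id}: invalid characters {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"record {self.id}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """One location segment: 1-based inclusive, optionally on another accession."""

    start: int
    end: int
    strand: str = "+"
    ref: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Feature:
    """A genome feature; intervals are stored in transcription order."""

    kind: str
    record_id: str
    location: list[Interval]
    qualifiers: dict[str, list[str]] = field(default_factory=dict)

    @property
    def strand(self) -> str:
        return self.location[0].strand

    @property
    def gene(self) -> str | None:
        for key in ("gene", "locus_tag"):
            if key in self.qualifiers:
                return self.qualifiers[key][0]
        return None

    def qualifier(self, key: str, default: str | None = None) -> str | None:
        vals = self.qualifiers.get(key)
        return vals[0] if vals else default

    def spliced_length(self) -> int:
        return sum(len(iv) for iv in self.location)


@dataclass
class AnnotatedEdit:
    """An :class:`EditingSite` anchored on the genome."""

    site: EditingSite
    record_id: str
    genome_pos: int  # 1-based, + strand coordinate of the edited nucleotide
    strand: str = "+"
    orphan: bool = False
    feature: Feature | None = None


@dataclass
class Editome:
    """An annotated organelle genome with its documented editing sites."""

    records: list[SequenceRecord]
    features: list[Feature] = field(default_factory=list)
    edits: list[AnnotatedEdit] = field(default_factory=list)
    organelle: str = ""
    species: str = ""
    unresolved_remotes: list[str] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.records[0].id if self.records else ""

    def record(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id or rec.id.split(".")[0] == record_id.split(".")[0]:
                return rec
        raise KeyError(record_id)

    def cds_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    def cds_sequence(self, feature: Feature) -> str:
        """Spliced sense-strand coding sequence of a CDS feature."""
        parts = []
        for iv in feature.location:
            rec = self.record(iv.ref) if iv.ref else self.record(feature.record_id)
            seg = rec.seq[iv.start - 1 : iv.end]
            if iv.strand == "-":
                seg = str(Seq(seg).reverse_complement())
            parts.append(seg)
        return "".join(parts)

    def cds_position_of(self, feature: Feature, record_id: str, genome_pos: int) -> int | None:
        """Map a genome position to its 1-based spliced-CDS coordinate.

        Honours strand, splicing and the reading-frame offset of partial CDS
        (``codon_start``).  Returns None when the position is not covered or
        falls before the frame start.
        """
        offset = 0
        pos0 = genome_pos - 1
        for iv in feature.location:
            iv_rec = iv.ref if iv.ref else feature.record_id
            same = iv_rec.split(".")[0] == record_id.split(".")[0]
            if same and iv.start <= genome_pos <= iv.end:
                if iv.strand == "+":
                    within = pos0 - (iv.start - 1)
                else:
                    within = (iv.end - 1) - pos0
                spliced0 = offset + within
                codon_start = int(feature.qualifier("codon_start", "1"))
                cds_pos = spliced0 - (codon_start - 1) + 1
                return cds_pos if cds_pos >= 1 else None
            offset += len(iv)
        return None

    def genome_position_of(self, feature: Feature, cds_pos: int) -> tuple[str, int, str] | None:
        """Inverse of :meth:`cds_position_of`: (record_id, genome_pos, strand)."""
        codon_start = int(feature.qualifier("codon_start", "1"))
        spliced0 = cds_pos - 1 + (codon_start - 1)
        offset = 0
        for iv in feature.location:
            if offset <= spliced0 < offset + len(iv):
                within = spliced0 - offset
                rec_id = iv.ref if iv.ref else feature.record_id
                if iv.strand == "+":
                    return rec_id, iv.start + within, "+"
                return rec_id, iv.end - within, "-"
            offset += len(iv)
        return None

    def applied_edits(self, direction: Direction | None = None) -> list[AnnotatedEdit]:
        out = []
        for e in self.edits:
            if not e.site.applied or e.orphan:
                continue
            if direction is not None and e.site.direction != Direction(direction):
                continue
            out.append(e)
        return out


# ---------------------------------------------------------------------------
# parsing


def _location_to_intervals(location, default_strand=1) -> list[Interval]:
    ivs = []
    for part in location.parts:
        strand = part.strand if part.strand is not None else default_strand
        ivs.append(
            Interval(
                start=int(part.start) + 1,
                end=int(part.end),
                strand="-" if strand == -1 else "+",
                ref=part.ref,
            )
        )
    return ivs


_KINDS = {"gene", "CDS", "RNA_editing", "Search_range", "Search_result"}


def parse_genbank(text: str, organelle: str | None = None) -> Editome:
    """Parse one or more concatenated GenBank records into an :class:`Editome`.

    Remote location segments are resolved against the other records of the
    same file; references to absent accessions are recorded in
    ``unresolved_remotes`` (use :func:`assemble_multichromosome` to merge
    further accessions).  ``RNA_editing`` features outside any CDS are kept
    as orphans and trigger a warning.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_records = list(SeqIO.parse(StringIO(text), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(str(exc)) from exc
    if not bio_records:
        raise GenBankParseError("no GenBank records found")

    records: list[SequenceRecord] = []
    features: list[Feature] = []
    species = ""
    org = organelle or ""
    for rec in bio_records:
        rec_id = rec.id if rec.id and rec.id != "<unknown id>" else rec.name
        records.append(
            SequenceRecord(
                id=rec_id,
                seq=str(rec.seq),
                topology=rec.annotations.get("topology", "linear"),
                description=rec.description if rec.description != "." else "",
            )
        )
        species = species or rec.annotations.get("organism", "")
        for bf in rec.features:
            if bf.type == "source":
                org = org or bf.qualifiers.get("organelle", [""])[0]
                species = species or bf.qualifiers.get("organism", [""])[0]
                continue
            if bf.type not in _KINDS:
                continue
            try:
                ivs = _location_to_intervals(bf.location)
            except (ValueError, AttributeError) as exc:
                raise GenBankParseError(
                    f"malformed location for {bf.type} in {rec_id}: {exc}"
                ) from exc
            features.append(
                Feature(
                    kind=bf.type,
                    record_id=rec_id,
                    location=ivs,
                    qualifiers={k: list(v) for k, v in bf.qualifiers.items()},
                )
            )

    editome = Editome(records=records, features=features, organelle=org, species=species)
    _derive_edits(editome)
    return editome


def _xref_ids(feature: Feature) -> list[int]:
    ids = []
    for val in feature.qualifiers.get("db_xref", []):
        if val.startswith("EdiFacts:"):
            try:
                ids.append(int(val.split(":", 1)[1]))
            except ValueError:
                pass
    return ids


def _derive_edits(editome: Editome) -> None:
    """Resolve RNA_editing features to CDS-relative :class:`EditingSite`s."""
    known = {rec.id.split(".")[0] for rec in editome.records}
    unresolved = []
    cds_list = editome.cds_features()
    for cds in cds_list:
        for iv in cds.location:
            if iv.ref and iv.ref.split(".")[0] not in known:
                unresolved.append(iv.ref)
    editome.unresolved_remotes = sorted(set(unresolved))
    resolvable = [
        cds
        for cds in cds_list
        if all(iv.ref is None or iv.ref.split(".")[0] in known for iv in cds.location)
    ]

    # pre-compute spliced sequences and per-CDS edit positions so that
    # codon_after reflects all edits of a codon
    cds_seqs = {id(c): editome.cds_sequence(c) for c in resolvable}
    cds_edit_positions: dict[int, dict[int, Direction]] = {id(c): {} for c in resolvable}

    edit_feats = [f for f in editome.features if f.kind == "RNA_editing"]
    placements: list[tuple[Feature, Feature | None, int | None, int, str]] = []
    for ef in edit_feats:
        iv = ef.location[0]
        genome_pos = iv.start
        host, cds_pos = None, None
        for cds in resolvable:
            if cds.strand != iv.strand:
                continue
            p = editome.cds_position_of(cds, ef.record_id, genome_pos)
            if p is not None and p <= len(cds_seqs[id(cds)]):
                host, cds_pos = cds, p
                break
        placements.append((ef, host, cds_pos, genome_pos, iv.strand))
        if host is not None:
            d = ef.qualifier("direction")
            if d is None:
                base = cds_seqs[id(host)][cds_pos - 1]
                d = Direction.C_TO_U if base == "C" else Direction.U_TO_C
            cds_edit_positions[id(host)][cds_pos] = Direction(d)

    for ef, host, cds_pos, genome_pos, strand in placements:
        applied = ef.qualifier("applied", "yes") == "yes"
        if host is None:
            warnings.warn(
                f"RNA_editing feature at {ef.record_id}:{genome_pos} lies outside "
                "any CDS; kept as orphan"
            )
            d = ef.qualifier("direction")
            if d is None:
                rec = editome.record(ef.record_id)
                base = rec.seq[genome_pos - 1]
                if strand == "-":
                    base = str(Seq(base).reverse_complement())
                d = Direction.C_TO_U if base == "C" else Direction.U_TO_C
            site = EditingSite(
                gene=ef.gene or ef.record_id,
                cds_pos=genome_pos,
                direction=Direction(d),
                applied=applied,
                db_xrefs=_xref_ids(ef),
            )
            editome.edits.append(
                AnnotatedEdit(site=site, record_id=ef.record_id,
                              genome_pos=genome_pos, strand=strand,
                              orphan=True, feature=ef)
            )
            continue

        # codon extraction is frame-relative: skip partial leading bases
        frame_off = int(host.qualifier("codon_start", "1")) - 1
        seq = cds_seqs[id(host)][frame_off:]
        direction = cds_edit_positions[id(host)][cds_pos]
        codon_idx, _ = codon_coords(cds_pos)
        c0 = (codon_idx - 1) * 3
        codon_before = seq[c0 : c0 + 3]
        if len(codon_before) < 3:
            codon_before = codon_before.ljust(3, "N")
        codon_after = list(codon_before)
        for p, d in cds_edit_positions[id(host)].items():
            if c0 < p <= c0 + 3:
                codon_after[p - 1 - c0] = d.edited_base
        transl_table = int(host.qualifier("transl_table", "1"))
        site = EditingSite(
            gene=host.gene or host.record_id,
            cds_pos=cds_pos,
            direction=direction,
            codon_before=codon_before,
            codon_after="".join(codon_after),
            applied=applied,
            db_xrefs=_xref_ids(ef),
            transl_table=transl_table,
        )
        editome.edits.append(
            AnnotatedEdit(site=site, record_id=ef.record_id,
                          genome_pos=genome_pos, strand=host.strand, feature=ef)
        )


# ---------------------------------------------------------------------------
# writing


def _intervals_to_location(ivs: list[Interval]):
    parts = [
        SimpleLocation(iv.start - 1, iv.end, strand=-1 if iv.strand == "-" else 1, ref=iv.ref)
        for iv in ivs
    ]
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def write_genbank(editome: Editome) -> str:
    """Serialise an :class:`Editome` as a GenBank flat-file string.

    ``parse_genbank(write_genbank(e))`` reproduces ``e`` up to qualifier
    ordering.
    """
    out = StringIO()
    bio_records = []
    for rec in editome.records:
        sr = SeqRecord(
            Seq(rec.seq),
            id=rec.id,
            name=rec.id.split(".")[0],
            description=rec.description or ".",
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = rec.topology
        sr.annotations["organism"] = editome.species
        src_quals = {"organism": [editome.species]} if editome.species else {}
        if editome.organelle:
            src_quals["organelle"] = [editome.organelle]
        sr.features.append(
            SeqFeature(SimpleLocation(0, len(rec.seq), strand=1), type="source",
                       qualifiers=src_quals)
        )
        for feat in editome.features:
            if feat.record_id != rec.id:
                continue
            sr.features.append(
                SeqFeature(
                    _intervals_to_location(feat.location),
                    type=feat.kind,
                    qualifiers={k: list(v) for k, v in feat.qualifiers.items()},
                )
            )
        bio_records.append(sr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        SeqIO.write(bio_records, out, "genbank")
    return out.getvalue()


def assemble_multichromosome(editomes: list[Editome]) -> Editome:
    """Merge per-chromosome editomes of one genome into a single editome.

    Remote CDS segments referring to any of the supplied accessions become
    resolvable; a reference to an accession present in none of them raises
    :class:`UnresolvedRemoteError`.
    """
    if not editomes:
        raise ValueError("no editomes to assemble")
    species = {e.species for e in editomes if e.species}
    organelle = {e.organelle for e in editomes if e.organelle}
    if len(species) > 1 or len(organelle) > 1:
        raise ValueError("editomes to assemble must share species and organelle")
    merged = Editome(
        records=[r for e in editomes for r in e.records],
        features=[f for e in editomes for f in e.features],
        organelle=next(iter(organelle), ""),
        species=next(iter(species), ""),
    )
    known = {rec.id.split(".")[0] for rec in merged.records}
    missing = [
        iv.ref
        for f in merged.features
        for iv in f.location
        if iv.ref and iv.ref.split(".")[0] not in known
    ]
    if missing:
        raise UnresolvedRemoteError(missing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _derive_edits(merged)
    return merged


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(text: str) -> list[SequenceRecord]:
    """Read (multi-)FASTA nucleotide text; gap characters are preserved only
    by :func:`read_alignment_fasta` in the prediction module."""
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        desc = "" if rec.description == rec.id else rec.description
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], width: int = 70) -> str:
    lines = []
    for rec in records:
        header = rec.id if not rec.description or rec.description == rec.id else rec.description
        lines.append(f">{header}")
        for i in range(0, len(rec.seq), width):
            lines.append(rec.seq[i : i + width])
    return "\n".join(lines) + "\n"
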
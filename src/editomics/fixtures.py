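"""Deterministic synthetic editomes, queries and matrices.

Every generator is a pure function of its seed: the same spec yields
byte-identical GenBank text.  Generated editomes have translatable CDS
features (ATG start, single terminal stop, no internal stops), per-site
``RNA_editing`` annotations consistent with their direction, optional
inverted-repeat-style gene duplication (the duplicate carries duplicated
edit annotations), a configurable strand mix, and a per-offset base-bias
model around edit positions so that context statistics can be emulated
(e.g. a uridine preference at -1).

The generated data emulate the *statistical* structure the analyses assume
(editing density, context bias, strand and duplication bookkeeping), not
organelle biology in detail; real editomes have introns, partial and
trans-spliced CDS and far longer genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from editomics import editome_io
from editomics.editome_io import Editome, Feature, Interval, SequenceRecord
from editomics.nomenclature import Direction
from editomics.ppr_code import CodeParams, PPRMotif, array_to_matrix
from editomics.targetscan import BASES, WeightMatrix

__all__ = [
    "FixtureSpec",
    "make_editome",
    "make_ppr98_like_array",
    "make_ppr98_like_matrix",
    "true_target_window",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic editome."""

    seed: int = 1
    n_genes: int = 2
    gene_length_codons: tuple[int, int] = (40, 80)  # inclusive range
    edits_per_gene: int = 3
    u_to_c_fraction: float = 0.0  # fraction of edits that are reverse U-to-C
    nonsynonymous_only: bool = True  # amino-acid-changing edits only
    context_bias: dict[int, dict[str, float]] = field(default_factory=dict)
    ir_duplication: bool = False
    minus_strand_fraction: float = 0.0
    spacer_length: int = 30
    accession: str = "SYN000001.1"
    species: str = "Synthetica exempli"
    organelle: str = "mitochondrion"


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in _STOPS:
            return codon


def _draw_base(rng: np.random.Generator, dist: dict[str, float]) -> str:
    bases = list(BASES)
    probs = np.array([dist.get(b, 0.0) for b in bases], dtype=float)
    probs = probs / probs.sum()
    return str(rng.choice(bases, p=probs))


def _make_gene(
    rng: np.random.Generator, spec: FixtureSpec, gene_name: str
) -> tuple[str, list[tuple[int, Direction]]]:
    """One in-frame CDS (sense orientation) and its edit positions (1-based)."""
    n_codons = int(rng.integers(spec.gene_length_codons[0], spec.gene_length_codons[1] + 1))
    codons = ["ATG"] + [_random_codon(rng) for _ in range(n_codons - 2)]
    seq = list("".join(codons) + "TAA")
    length = len(seq)

    # candidate edit positions: keep a margin so the -4..+3 context and the
    # start/stop codons never collide, and space edits >= 8 nt apart
    margin = 9
    offsets = sorted(spec.context_bias)
    chosen: list[int] = []
    directions: list[Direction] = []
    order = rng.permutation(np.arange(margin + 1, length - margin))
    for pos in order:
        if len(chosen) >= spec.edits_per_gene:
            break
        if any(abs(pos - c) < 8 for c in chosen):
            continue
        if spec.nonsynonymous_only and (pos - 1) % 3 == 2:
            continue  # third-position pyrimidine exchanges are always silent
        chosen.append(int(pos))
        d = (
            Direction.U_TO_C
            if rng.random() < spec.u_to_c_fraction
            else Direction.C_TO_U
        )
        directions.append(d)
    if len(chosen) < spec.edits_per_gene:
        raise ValueError(
            f"infeasible spec: cannot place {spec.edits_per_gene} edits in a "
            f"{length} nt gene"
        )

    for pos, d in zip(chosen, directions):
        seq[pos - 1] = d.genomic_base
        for off in offsets:
            tpos = pos + off
            if 1 <= tpos <= length and tpos not in chosen:
                seq[tpos - 1] = _draw_base(rng, spec.context_bias[off])

    constrained = set(chosen)
    for pos in chosen:
        for off in offsets:
            constrained.add(pos + off)

    if spec.nonsynonymous_only:
        from editomics.nomenclature import translate_codon

        for pos, d in zip(chosen, directions):
            c0 = ((pos - 1) // 3) * 3
            within = pos - 1 - c0

            def _ok(codon: str) -> bool:
                after = list(codon)
                after[within] = d.edited_base
                aa_b = translate_codon(codon)
                aa_a = translate_codon("".join(after))
                return aa_b not in ("*",) and aa_a != "*" and aa_b != aa_a

            codon = "".join(seq[c0 : c0 + 3])
            if _ok(codon):
                continue
            fixed = None
            for w in (0, 1, 2):
                if w == within or (c0 + w + 1) in constrained:
                    continue
                for b in "ACGT":
                    trial = list(codon)
                    trial[w] = b
                    if _ok("".join(trial)):
                        fixed = "".join(trial)
                        break
                if fixed:
                    break
            if fixed is None:
                raise ValueError(
                    "infeasible spec: cannot make edit at position "
                    f"{pos} amino-acid-changing"
                )
            seq[c0 : c0 + 3] = list(fixed)

    # repair internal stop codons created by edit/bias substitutions
    for ci in range(1, length // 3 - 1):
        c0 = ci * 3
        codon = "".join(seq[c0 : c0 + 3])
        if codon not in _STOPS:
            continue
        for within in (0, 1, 2):
            p = c0 + within + 1
            if p in constrained:
                continue
            for b in "ACG":
                trial = list(codon)
                trial[within] = b
                if "".join(trial) not in _STOPS:
                    seq[c0 + within] = b
                    break
            break
        else:
            raise ValueError("infeasible spec: fully constrained stop codon")
    pairs = sorted(zip(chosen, directions))
    return "".join(seq), pairs


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_editome(spec: FixtureSpec) -> tuple[Editome, str]:
    """Generate a synthetic editome; returns (Editome, GenBank text).

    The Editome is obtained by parsing the generated text, so the two are
    consistent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[dict] = []
    for gi in range(spec.n_genes):
        name = f"gen{gi + 1}"
        cds, edits = _make_gene(rng, spec, name)
        minus = rng.random() < spec.minus_strand_fraction
        genes.append({"name": name, "cds": cds, "edits": edits, "minus": minus})
    if spec.ir_duplication and genes:
        dup = dict(genes[0])
        dup["minus"] = not genes[0]["minus"]
        genes.append(dup)

    genome_parts: list[str] = []
    features: list[Feature] = []
    cursor = 0  # 0-based length so far

    def spacer() -> str:
        return "".join(rng.choice(list("ACGT"), size=spec.spacer_length))

    acc = spec.accession
    for g in genes:
        genome_parts.append(spacer())
        cursor += spec.spacer_length
        cds = g["cds"]
        seg = _revcomp(cds) if g["minus"] else cds
        start = cursor + 1
        end = cursor + len(seg)
        strand = "-" if g["minus"] else "+"
        loc = [Interval(start, end, strand)]
        features.append(
            Feature(kind="gene", record_id=acc, location=loc,
                    qualifiers={"gene": [g["name"]]})
        )
        features.append(
            Feature(
                kind="CDS", record_id=acc, location=loc,
                qualifiers={"gene": [g["name"]], "transl_table": ["1"],
                            "codon_start": ["1"]},
            )
        )
        for cds_pos, d in g["edits"]:
            gpos = start + cds_pos - 1 if strand == "+" else end - cds_pos + 1
            features.append(
                Feature(
                    kind="RNA_editing", record_id=acc,
                    location=[Interval(gpos, gpos, strand)],
                    qualifiers={"direction": [d.value], "applied": ["yes"]},
                )
            )
        genome_parts.append(seg)
        cursor += len(seg)
    genome_parts.append(spacer())
    genome = "".join(genome_parts)

    skeleton = Editome(
        records=[SequenceRecord(id=acc, seq=genome)],
        features=features,
        species=spec.species,
        organelle=spec.organelle,
    )
    text = editome_io.write_genbank(skeleton)
    editome = editome_io.parse_genbank(text)
    return editome, text


# ---------------------------------------------------------------------------
# PPR-array example matrix


def make_ppr98_like_array() -> list[PPRMotif]:
    """A 21-repeat PLS array shaped like a typical DYW-type editing factor.

    Twelve of its P/S repeats conform to the recognition code — seven
    purine-selective and five pyrimidine-selective — while the L-type
    repeats, one non-canonical S repeat and the divergent terminal S2 repeat
    contribute nothing (weight-0 columns).
    """
    plan: list[tuple[int, str, str, str]] = []
    # reverse indices 21..1; repeating P,L,S from the 5' end, terminal S2
    purine_assign = {21: ("T", "N"), 18: ("T", "N"), 15: ("T", "D"),
                     12: ("T", "N"), 9: ("S", "N"), 6: ("T", "D"), 3: ("T", "N")}
    pyrimidine_assign = {19: ("N", "S"), 16: ("N", "D"), 13: ("N", "N"),
                         10: ("N", "D"), 7: ("N", "S")}
    for ri in range(21, 0, -1):
        cycle = (21 - ri) % 3  # 0 -> P, 1 -> L, 2 -> S
        if ri == 1:
            plan.append((ri, "S2", "G", "G"))
        elif cycle == 0:
            plan.append((ri, "P", *purine_assign[ri]))
        elif cycle == 1:
            plan.append((ri, "L", "V", "I"))
        else:
            if ri in pyrimidine_assign:
                plan.append((ri, "S", *pyrimidine_assign[ri]))
            else:  # non-canonical S repeat (ri == 4)
                plan.append((ri, "S", "K", "K"))
    return [PPRMotif(ri, t, a5, aL) for ri, t, a5, aL in plan]


def make_ppr98_like_matrix(params: CodeParams | None = None) -> WeightMatrix:
    """Scan matrix from :func:`make_ppr98_like_array` with the default code
    weighting, the empirical -1 column and an anchor column over the
    candidate edited C.  Maximum score 1655 without, 1855 with a +200
    edited-C bonus."""
    return array_to_matrix(
        make_ppr98_like_array(), params=params, append_minus1=True,
        anchor_bonus=True, name="PPR98_like",
    )


def true_target_window(matrix: WeightMatrix) -> str:
    """The documented-target-like window for a code-derived matrix.

    Perfect at every weighted column except three mismatches: the first
    purine-selective column carries the non-preferred purine (transition),
    the first pyrimidine-selective column carries a purine (transversion),
    and the second pyrimidine-selective column carries the non-preferred
    pyrimidine (transition).  The -1 column carries U and the anchor carries
    the candidate C.  Scores 1385 against the default matrix.
    """
    window: list[str] = []
    purine_seen = 0
    pyrimidine_seen = 0
    for col in matrix.columns:
        if col.is_anchor:
            window.append("C")
            continue
        if col.weight == 0:
            window.append("A")
            continue
        ranked = sorted(BASES, key=lambda b: (-col.values[b], b))
        preferred = ranked[0]
        if col.values[preferred] == 45:  # the empirical -1 profile: U
            window.append("T")
            continue
        if preferred in "AG":
            purine_seen += 1
            if purine_seen == 1:
                window.append("G" if preferred == "A" else "A")
            else:
                window.append(preferred)
        else:
            pyrimidine_seen += 1
            if pyrimidine_seen == 1:
                window.append("A")  # transversion: a purine at a pyrimidine column
            elif pyrimidine_seen == 2:
                window.append("T" if preferred == "C" else "C")
            else:
                window.append(preferred)
    return "".join(window)
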
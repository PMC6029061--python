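"""Catalogue of characterized PPR editing factors and site crosslinks.

Each record describes one nuclear-encoded editing factor: species,
organelle, its target editing sites (as nomenclature labels), repeat count
and C-terminal domain composition (E1/E2/DYW), a protein reference and the
describing publications.  The store is a flat JSON file.  Records can be
queried with per-field AND/OR logic (values may be glob patterns, e.g.
``gene="ccmF*"``), and an editome's matching ``RNA_editing`` features gain a
``/db_xref="EdiFacts:<id>"`` qualifier through :func:`crosslink` so that
downstream outputs can highlight sites with a known factor.

A small demo store with the two Physcomitrella patens ccmFC factors
(ids 44/45) ships with the package.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field, asdict
from importlib import resources

from editomics.editome_io import Editome
from editomics.nomenclature import parse_label

__all__ = [
    "FactorRecord",
    "FactorStore",
    "load_store",
    "demo_store",
    "query",
    "crosslink",
]

_CTERM = {"E1", "E2", "DYW"}


@dataclass
class FactorRecord:
    id: int
    name: str
    species: str
    organelle: str
    target_sites: list[tuple[str, str]]  # (gene, site label)
    n_ppr: int = 0
    c_terminal: list[str] = field(default_factory=list)
    protein_ref: str = ""
    publications: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.target_sites = [tuple(t) for t in self.target_sites]
        bad = set(self.c_terminal) - _CTERM
        if bad:
            raise ValueError(f"unknown C-terminal domains {sorted(bad)}")
        for _, label in self.target_sites:
            parse_label(label)  # every target label must parse


@dataclass
class FactorStore:
    records: list[FactorRecord]
    synonyms: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate factor ids in store")

    def gene_aliases(self, gene: str) -> set[str]:
        """The gene plus all synonyms reachable from it (symmetric closure)."""
        groups = [set([k, *v]) for k, v in self.synonyms.items()]
        aliases = {gene}
        changed = True
        while changed:
            changed = False
            for g in groups:
                if aliases & g and not g <= aliases:
                    aliases |= g
                    changed = True
        return aliases

    def to_json(self) -> str:
        return json.dumps(
            {"records": [asdict(r) for r in self.records], "synonyms": self.synonyms},
            indent=1,
        )


def load_store(text: str) -> FactorStore:
    data = json.loads(text)
    return FactorStore(
        records=[FactorRecord(**r) for r in data["records"]],
        synonyms=data.get("synonyms", {}),
    )


def demo_store() -> FactorStore:
    """The packaged demo store (Physcomitrella ccmFC factors, ids 44/45)."""
    text = resources.files("editomics.data").joinpath("edifacts_demo.json").read_text()
    return load_store(text)


_QUERY_FIELDS = {
    "id", "name", "species", "organelle", "gene", "site",
    "n_ppr", "c_terminal", "author",
}


def _field_values(rec: FactorRecord, store: FactorStore, fieldname: str) -> list[str]:
    if fieldname == "id":
        return [str(rec.id)]
    if fieldname == "name":
        return [rec.name]
    if fieldname == "species":
        return [rec.species]
    if fieldname == "organelle":
        return [rec.organelle]
    if fieldname == "gene":
        genes: set[str] = set()
        for g, _ in rec.target_sites:
            genes |= store.gene_aliases(g)
        return sorted(genes)
    if fieldname == "site":
        return [label for _, label in rec.target_sites]
    if fieldname == "n_ppr":
        return [str(rec.n_ppr)]
    if fieldname == "c_terminal":
        return list(rec.c_terminal)
    if fieldname == "author":
        return list(rec.publications)
    raise KeyError(fieldname)


def _match(values: list[str], pattern: str) -> bool:
    pat = pattern.lower()
    return any(
        fnmatch.fnmatch(v.lower(), pat) or pat in v.lower() for v in values
    )


def query(
    store: FactorStore,
    filters: dict[str, str | list[str]],
    logic: str | dict[str, str] = "AND",
) -> list[FactorRecord]:
    """Filter factor records with per-field boolean logic.

    ``filters`` maps a field name to one pattern or a list of patterns;
    within a field, list entries combine with OR.  Across fields, ``logic``
    (a single "AND"/"OR" or a per-field map with key ``"__fields__"``)
    combines the field verdicts; the default is AND across fields, matching
    e.g. species="Physcomitrella patens" AND gene="ccmF*".  Patterns match
    case-insensitively as substrings or fnmatch globs.
    """
    unknown = set(filters) - _QUERY_FIELDS
    if unknown:
        raise KeyError(f"unknown query field(s): {sorted(unknown)}")
    field_logic = logic if isinstance(logic, str) else logic.get("__fields__", "AND")
    if field_logic not in ("AND", "OR"):
        raise ValueError("logic must be AND or OR")
    out = []
    for rec in store.records:
        verdicts = []
        for fieldname, patterns in filters.items():
            pats = [patterns] if isinstance(patterns, str) else list(patterns)
            values = _field_values(rec, store, fieldname)
            verdicts.append(any(_match(values, p) for p in pats))
        if not filters:
            keep = True
        elif field_logic == "AND":
            keep = all(verdicts)
        else:
            keep = any(verdicts)
        if keep:
            out.append(rec)
    return sorted(out, key=lambda r: r.id)


def factors_for_label(store: FactorStore, label: str, species: str = "",
                      organelle: str = "") -> list[FactorRecord]:
    """All factors targeting a site label (gene-synonym aware)."""
    gene, cds_pos, direction, _, _ = parse_label(label)
    aliases = {a.lower() for a in store.gene_aliases(gene)}
    hits = []
    for rec in store.records:
        if species and rec.species.lower() != species.lower():
            continue
        if organelle and rec.organelle != organelle:
            continue
        for tgene, tlabel in rec.target_sites:
            tg, tpos, tdir, _, _ = parse_label(tlabel)
            if tg.lower() in aliases and tpos == cds_pos and tdir == direction:
                hits.append(rec)
                break
    return sorted(hits, key=lambda r: r.id)


def crosslink(editome: Editome, store: FactorStore) -> Editome:
    """Attach ``/db_xref="EdiFacts:<id>"`` to every annotated site with a
    known factor.  Ambiguous multi-factor matches attach all ids; the
    operation is idempotent."""
    for edit in editome.edits:
        if edit.orphan or edit.feature is None:
            continue
        matches = factors_for_label(
            store, edit.site.label, species=editome.species, organelle=editome.organelle
        )
        if not matches:
            continue
        xrefs = edit.feature.qualifiers.setdefault("db_xref", [])
        for rec in matches:
            tag = f"EdiFacts:{rec.id}"
            if tag not in xrefs:
                xrefs.append(tag)
            if rec.id not in edit.site.db_xrefs:
                edit.site.db_xrefs.append(rec.id)
    return editome
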
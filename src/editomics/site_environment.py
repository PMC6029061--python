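"""Nucleotide composition in the immediate neighbourhood of editing sites.

For every applied edit of one direction, the genomic (pre-editing) bases at
offsets -4..+3 around the edited nucleotide are counted in transcript sense
orientation (offset 0, the edited base itself, is excluded).  Per-position
frequencies are reported in percent to one decimal, and shaded ``red`` below
10% or ``green`` above 50% — strong depletions and preferences such as the
near-absence of G and the dominance of U at -1 upstream of C-to-U edits.
Sites whose window is truncated by a sequence end are excluded per position
and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from editomics.editome_io import Editome
from editomics.nomenclature import Direction
from editomics.targetscan import BASES

__all__ = ["ContextTable", "context_table", "compare_directions", "DEFAULT_WINDOW"]

DEFAULT_WINDOW = tuple(o for o in range(-4, 4) if o != 0)

RED_BELOW = 10.0
GREEN_ABOVE = 50.0


@dataclass
class ContextTable:
    """Per-position base counts/frequencies around editing sites."""

    dataset: str
    direction: Direction
    n_sites: int
    counts: dict[int, dict[str, int]]
    truncated: dict[int, int] = field(default_factory=dict)

    @property
    def window(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))

    def frequencies(self) -> dict[int, dict[str, float]]:
        """Percent per base and position, rounded to one decimal."""
        out: dict[int, dict[str, float]] = {}
        for pos, row in self.counts.items():
            total = sum(row.values())
            out[pos] = {
                b: (round(100 * row[b] / total, 1) if total else 0.0) for b in BASES
            }
        return out

    def shading(self) -> dict[int, dict[str, str | None]]:
        """'red' (<10%), 'green' (>50%) or None per cell."""
        out: dict[int, dict[str, str | None]] = {}
        for pos, row in self.frequencies().items():
            out[pos] = {}
            for b, f in row.items():
                if f < RED_BELOW:
                    out[pos][b] = "red"
                elif f > GREEN_ABOVE:
                    out[pos][b] = "green"
                else:
                    out[pos][b] = None
        return out

    def to_html(self) -> str:
        """Minimal colour-annotated HTML table (red <10%, green >50%)."""
        freqs, shades = self.frequencies(), self.shading()
        css = ("<style>td.red{background:#f8b4b4}td.green{background:#b4f8b4}"
               "table{border-collapse:collapse}td,th{border:1px solid #999;"
               "padding:2px 6px}</style>")
        head = "".join(f"<th>{p:+d}</th>" for p in self.window)
        body = []
        for b in BASES:
            cells = []
            for p in self.window:
                cls = shades[p][b] or ""
                cells.append(
                    f'<td class="{cls}">{self.counts[p][b]} ({freqs[p][b]}%)</td>'
                )
            body.append(f"<tr><th>{'U' if b == 'T' else b}</th>{''.join(cells)}</tr>")
        return (
            f"{css}<h3>{self.dataset} — {self.direction.value} "
            f"(n={self.n_sites})</h3><table><tr><th></th>{head}</tr>"
            + "".join(body) + "</table>"
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: position, base, count, percent, shading."""
        freqs, shades = self.frequencies(), self.shading()
        rows = []
        for pos in self.window:
            for b in BASES:
                rows.append(
                    {
                        "dataset": self.dataset,
                        "direction": self.direction.value,
                        "position": pos,
                        "base": "U" if b == "T" else b,
                        "count": self.counts[pos][b],
                        "percent": freqs[pos][b],
                        "shading": shades[pos][b] or "",
                    }
                )
        return pd.DataFrame(rows)


def context_table(
    editomes: list[Editome],
    direction: Direction,
    window: tuple[int, ...] = DEFAULT_WINDOW,
    dataset: str = "",
    apply_neighbors: bool = False,
    applied_only: bool = True,
) -> ContextTable:
    """Count sense-strand context bases around every edit of ``direction``.

    ``apply_neighbors`` substitutes the edited base at neighbouring edited
    positions before counting (off by default: context is genomic).
    """
    direction = Direction(direction)
    if 0 in window:
        raise ValueError("the window must exclude position 0 (the edited base)")
    counts = {pos: {b: 0 for b in BASES} for pos in window}
    truncated = {pos: 0 for pos in window}
    n_sites = 0
    for ed in editomes:
        edit_map: dict[tuple[str, str, int], Direction] = {}
        if apply_neighbors:
            for e in ed.edits:
                if e.orphan or (applied_only and not e.site.applied):
                    continue
                edit_map[(e.record_id, e.strand, e.genome_pos)] = e.site.direction
        for e in ed.edits:
            if e.orphan:
                continue
            if applied_only and not e.site.applied:
                continue
            if e.site.direction != direction:
                continue
            n_sites += 1
            rec = ed.record(e.record_id)
            n = len(rec.seq)
            for off in window:
                # transcript-sense offset -> genome coordinate
                gpos = e.genome_pos + off if e.strand == "+" else e.genome_pos - off
                if not (1 <= gpos <= n):
                    truncated[off] += 1
                    continue
                base = rec.seq[gpos - 1]
                if e.strand == "-":
                    base = str(Seq(base).reverse_complement())
                d = edit_map.get((e.record_id, e.strand, gpos))
                if d is not None:
                    base = d.edited_base
                if base in counts[off]:
                    counts[off][base] += 1
                else:  # N or ambiguity: excluded like a truncation
                    truncated[off] += 1
    return ContextTable(
        dataset=dataset or (editomes[0].species if editomes else ""),
        direction=direction,
        n_sites=n_sites,
        counts=counts,
        truncated={k: v for k, v in truncated.items() if v},
    )


def compare_directions(t1: ContextTable, t2: ContextTable) -> pd.DataFrame:
    """Per-position frequency differences (t1 - t2) and dominant-base switches.

    Positions where one table is empty are flagged NA rather than compared.
    """
    if t1.window != t2.window:
        raise ValueError("context tables have different windows")
    f1, f2 = t1.frequencies(), t2.frequencies()
    rows = []
    for pos in t1.window:
        empty = sum(t1.counts[pos].values()) == 0 or sum(t2.counts[pos].values()) == 0
        diffs = {b: round(f1[pos][b] - f2[pos][b], 1) for b in BASES}
        dom1 = max(BASES, key=lambda b: f1[pos][b])
        dom2 = max(BASES, key=lambda b: f2[pos][b])
        rows.append(
            {
                "position": pos,
                **{f"d{'U' if b == 'T' else b}": (float("nan") if empty else diffs[b]) for b in BASES},
                "max_abs_diff": float("nan") if empty else max(abs(v) for v in diffs.values()),
                "dominant_1": "U" if dom1 == "T" else dom1,
                "dominant_2": "U" if dom2 == "T" else dom2,
                "dominant_switch": (not empty) and dom1 != dom2,
            }
        )
    df = pd.DataFrame(rows)
    return df
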
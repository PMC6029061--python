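# editomics

Offline toolkit for analysing **plant-type RNA editing** in chloroplast and
mitochondrial genomes: prediction and cataloguing of C-to-U (and reverse
U-to-C) editing sites against annotated reference editomes, position-weighted
scanning for the RNA targets of PPR editing factors, and statistics on the
sequence environment of editing sites.

## Who this is for

Organelle genomicists and RNA-editing researchers who need to

- predict candidate editing sites in an unannotated organelle sequence, cDNA
  or multiple alignment by translated homology against *reference editomes*
  (annotated genomes whose documented editing events are carried as
  per-nucleotide `RNA_editing` features in GenBank flat files);
- translate an annotated PLS-type PPR protein into a position weight matrix
  via the empirical PPR–RNA recognition code and rank candidate binding
  sites across genomes, coding regions, or windows anchored at documented
  edits;
- tabulate nucleotide bias at positions −4..+3 around editing sites;
- query a catalogue of characterized editing factors and crosslink factor
  records to editing-site annotations.

Everything runs offline from local files; no web service or database server
is involved.

## The core models

**Homology prediction.** A query codon is a candidate editing site when
converting a non-empty subset of its C positions to U (or T→C for reverse
editing) yields the amino acid that homologous references encode at the
orthologous position. The query's six-frame translation is locally aligned
(BLOSUM62, affine gaps) against each reference's *edited* protein. Each
reference then renders one of five verdicts per codon: prediction via a
documented edit (shown RED), prediction via a genomically pre-edited codon
(BLACK), retention of the unedited amino acid, an inconvertible codon, or —
only when homology is lacking — a hyphen. Per-site support,
`100 × predicting / homologous` references, is aggregated into the *commons*
table and filtered at a display threshold (default 70%), with options to
keep sub-threshold sites documented in at least one reference, to restrict
to known sites, and to propose U-to-C edits that remove query stop codons.

**Position-weighted scanning.** A scan matrix assigns each position integer
base percentages summing to 100 plus an integer position weight; a window's
score is `Σ value(base) × weight / 100`, computed exactly in integer
hundredths. Hits are ranked by descending score; past the requested `top_n`,
all equal-scoring hits are kept so equally good matches are never cut
arbitrarily. The PPR–RNA code maps repeat residues (position 5: T/S purine
vs N pyrimidine; position L: D keto vs N amino) to per-repeat columns —
purines split 90/10 at weight 200, pyrimidines 70/30 at weight 100, the −1
position gets an empirical 15/35/5/45 profile — and an anchor column marks
the candidate edited C, which can receive a flat score bonus (e.g. +200).

## Worked example

Generate a synthetic two-gene reference editome and predict its own genome
against it (every documented site should be recovered at 100% support):

```sh
editomics fixtures --seed 1 --out fx
editomics predict --refs fx/editome.gb --query query.fasta --out pred
```

With `query.fasta` holding the fixture genome, `pred/commons_selfquery.tsv`
contains six rows, one per annotated site, e.g.:

```
label        gene  direction  ...  support_percent  included_by  SYN000001.1
gen1eU34PS   gen1  C_to_U     ...  100.0            threshold    RED:S
gen2eU80PL   gen2  C_to_U     ...  100.0            threshold    RED:L
```

`gen1eU34PS` reads: gene *gen1*, editing introduces a U at coding position
34, converting a proline codon (CCA) into a serine codon (TCA). `RED:S`
means the reference supports the site through its own documented edit whose
edited state encodes serine; support is 100% because the single homologous
reference predicts the site.

Scan the bundled PPR-code-derived example matrix around the documented
edits, with the +200 bonus for a cytidine at the anchor:

```sh
editomics targetscan --matrix fx/ppr98_like_matrix.tsv \
    --sources fx/editome.gb --mode edit_anchored --bonus 200 --out scan
```

The report's `max_score` column shows 1855 (1655 without the bonus), and the
best fixture window scores 875 — barely half the attainable maximum, as
expected for a motif unrelated to these random sequences. A window matching
the matrix perfectly at nine code positions with one purine-transition, one
pyrimidine-transition and one transversion mismatch and U at −1 scores 1385.

## The `RNA_editing` feature dialect

This package reads and writes editing annotations as GenBank features of
kind `RNA_editing` whose location is the single edited nucleotide on the
genome (on the CDS strand), with qualifiers `/direction="C_to_U"|"U_to_C"`
(inferred from the genomic base when absent), `/label`, `/applied="yes"|"no"`
(default yes) and optional `/db_xref="EdiFacts:<id>"` crosslinks to factor
records. Unknown qualifiers are preserved verbatim. This is this
repository's own dialect of the per-site annotation idea; the parser is
deliberately lenient about extra qualifiers. CDS features may use `join()`
locations, segments in other accessions (resolved via
`assemble_multichromosome`) and `codon_start` frame offsets.

## Command-line interface

`editomics` has eight subcommands: `predict` (translated-homology mode),
`alignmode` (pre-aligned multi-sequence prediction), `cdna` (genomic/cDNA
edit calling), `targetscan`, `pprmatrix` (PPR array → weight matrix),
`context` (−4..+3 environment tables), `edifacts` (factor catalogue query
and crosslinking) and `fixtures` (synthetic data bundles). All write TSV
with a JSON sidecar plus a `run_config.json` provenance record; outputs are
byte-identical across re-runs with the same inputs and seed.

See `docs/methods.md` for the scientific and numerical details.
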
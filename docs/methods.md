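# Methods

## Background and scope

Transcripts of plant chloroplasts and mitochondria undergo site-specific
C-to-U editing — and, in some lineages (hornworts, ferns, lycophytes),
reverse U-to-C editing — mostly restoring conserved codons in
protein-coding genes. The sites are addressed by nuclear-encoded PLS-type
pentatricopeptide-repeat (PPR) proteins with E1/E2/DYW C-terminal domains.
This package implements the computational layer connecting three kinds of
objects: annotated *editomes* (organelle genomes carrying per-nucleotide
`RNA_editing` features), *queries* (unannotated sequence, cDNA or
alignments) and *editing factors* (PPR proteins and their weight-matrix
representations).

## Editome model and coordinates

A reference editome is one or more GenBank records plus gene/CDS/
`RNA_editing` features. Externally all coordinates are 1-based inclusive
GenBank coordinates; splicing (`join`), minus-strand features, segments in
other accessions and `codon_start` frame offsets are honoured, so an edit's
`cds_pos` is always the 1-based position in the spliced, sense-orientation,
frame-corrected coding sequence. Edits on minus-strand CDS are therefore
reported in transcript orientation. Genomes split over several accessions
are merged with `assemble_multichromosome`, which resolves cross-accession
CDS segments and fails loudly, naming any accession still missing.
`RNA_editing` features outside every CDS are kept as orphans (they get
gene + genome-position fallback labels) and trigger a warning. Sequence is
stored as DNA (T); U is accepted on input.

Site labels follow the gene + `e` + introduced nucleotide + coding position
+ amino acids before/after convention (`atp9eU92SL`). Two conventions are
this package's own choices because no printed example covers them: stop
codons are rendered `X` in labels (configurable), and silent edits repeat
the amino acid (`…eU276SS`). When two nucleotides of one codon are edited,
each edited nucleotide carries its own site record and the amino acid after
editing reflects the fully edited codon — matching the per-site granularity
of the annotations.

## Homology-based prediction

For each reference gene we build the *genomic protein* (translation before
editing) and the *edited protein* (translation after applying all
`/applied="yes"` edits), with a per-residue back-map to codons and edit
records. The query's six reading frames are translated and locally aligned
against every edited protein with Biopython's `PairwiseAligner` (BLOSUM62,
gap open −11, extend −1); alignments below a raw-score floor (default 60)
or identity floor (default 0.35) are discarded, and overlapping hits from
the same reference keep only the highest score (ties break
lexicographically by reference id, then gene). These defaults are this
package's documented choices; they are deliberately conservative for short
organelle genes and are configurable through `SearchParams`.

Each aligned codon column yields one of five cell states, decided in this
order: `unedited_retained` if the query amino acid already equals the
reference's; otherwise `edited_in_ref` or `pre_edited_in_ref` if some
editable variant of the query codon (all non-empty C→T or T→C subsets, up
to 7 per codon, enumerated exhaustively) translates to the reference amino
acid — RED if the reference itself reached that amino acid by a documented
edit, BLACK if it encodes it genomically; otherwise `inconvertible`.
`no_homology` (the hyphen) is reserved for columns the reference does not
align to at all; a reference aligned to the gene but gapped at the precise
codon is likewise treated as lacking homology at that site, since it
contributes no amino-acid evidence there. When several conversions reach
the target amino acid, the one changing fewest nucleotides wins (then
C-to-U before U-to-C, then lexicographic) — a parsimony tie-break.

Commons rows aggregate cells across references per query codon. Support is
`100 × predicting / homologous`; the display threshold defaults to 70%, the
`recheck` preset (80% or at least one edited reference) flags strong
candidates for re-examination. Sub-threshold rows survive only with the
"always include reference sites" option when at least one reference is
edited at the site. Candidate labels use the gene name and codon numbering
of the lead predicting reference (best alignment score), so orthologous
positions are numbered consistently with the reference literature; the two
search directions are independent options. Stop-removal prognosis adds a
U-to-C row for every query stop codon convertible to a sense codon
regardless of reference support, preferring conversions that restore
arginine or glutamine (e.g. TGA→CGA), then fewest changes.

The alignment mode takes an equal-length gapped nucleotide alignment of one
gene whose reference rows are in-frame CDS of annotated editomes: documented
edits map through the gap structure to alignment columns, every other row is
classified at those columns with the same cell logic, and columns where the
number of edited-plus-predicted rows reaches a share threshold (default 2)
are flagged for shading. The cDNA mode calls edits from a pre-aligned
genomic/cDNA pair: C→T mismatches are C-to-U events, T→C mismatches U-to-C
events, anything else is reported separately and never called an edit;
silent events (third-position and first-position leucine YUR codons) are
classified for downstream display.

## Weight matrices and scanning

A matrix column holds integer base percentages summing to 100 and an
integer position weight. Column input mimics lock-and-redistribute
normalization: locked values are kept and the remainder is split evenly over
unlocked bases, any integer remainder going to the earlier bases in A,C,G,T
order (deterministic; locking A=15, C=35, G=5 auto-assigns T=45). Window
scores are `Σ value × weight / 100`, computed in exact integer hundredths —
for the parameter grids used here all scores are integers and no floating
point enters the comparison path. `N` scores 0.

Scanning modes: `genome` slides over every position (both strands by
default — the choice is exposed via `--strand`; windows running off a
linear sequence are skipped, circular topology wraps); `cds` slides over
each spliced CDS in sense orientation; `edit_anchored` evaluates exactly
one matrix-length window per documented edit with the anchor column over
the edited base (windows truncated by a CDS end are skipped). The anchor
bonus (e.g. +200) is added whenever the base under the anchor is C. Ranking
is total-descending with a deterministic (source id, strand, start)
tie-break; with tie-inclusion, all hits scoring equal to the `top_n`-th are
returned. Per-column colour categories interpolate linearly between the
column minimum (red) and maximum (green); zero-weight columns are skipped.
Scanned ranges and hits can be written back as `Search_range` /
`Search_result` GenBank features.

## The PPR recognition code

Per repeat, amino acids at positions 5 and L select the target nucleotide:
T/S+N→A, T/S+D→G, N+N/S→C, N+D→U. Purine selection is sharper than
pyrimidine selection, expressed by the default `CodeParams`: 90/10 at
weight 200 for purines, 70/30 at weight 100 for pyrimidines; L-type, the
divergent terminal S2 repeat and non-canonical residue combinations yield
neutral columns at weight 0 (a `noncanonical_weight` knob exists and cannot
change the ranking of windows that agree at those positions). The −1
position is not read by a repeat and gets the empirical pyrimidine-biased
15/35/5/45 profile at weight 100. Repeats are numbered in reverse (1 = last
repeat); the array is laid out 5'→3' by descending reverse index, the last
repeat's column ending immediately 5' of −1, followed by the −1 column and
the anchor. Because the exact repeat-to-nucleotide register is an empirical
convention rather than a printed rule, it is exposed as `register_offset`
instead of hard-coded. No columns are generated for E1/E2/DYW domains,
whose binding contribution is unknown.

The packaged example matrix (7 purine-selective, 5 pyrimidine-selective
code columns among 21 repeats) has maximum score
7·(90·200/100) + 5·(70·100/100) + 45 = 1655, rising to 1855 with the +200
anchor bonus, and its documented-target-like window — perfect except one
purine transition (−160), one pyrimidine transition (−40) and one
transversion at a pyrimidine column (−70), with U at −1 — scores 1385.
These three numbers are what `scripts/acceptance.py` recomputes.

## Site-environment statistics

For every applied edit of one direction, the genomic (pre-editing) bases at
offsets −4..+3 (excluding 0) are counted in transcript sense orientation.
Neighbouring edited positions are *not* substituted by default — the
context is genomic — because either convention is defensible; the
`apply_neighbors` flag flips it. Sites truncated at a sequence end are
excluded per position and reported. Frequencies are percentages to one
decimal; cells below 10% shade red and above 50% green. Direction
comparison reports per-position frequency differences and dominant-base
switches, flagging positions NA when one side has no sites.

## Synthetic data

The fixture generator is a pure function of its seed (NumPy
`default_rng`): genes of 40–80 codons (ATG start, single terminal stop, no
internal stops), a configurable number of edits per gene placed ≥8 nt apart
and ≥10 nt from gene ends, a direction mix, a strand mix, optional
inverted-repeat-style duplication (the duplicate carries duplicated edit
annotations), and a per-offset base-bias model around edit positions.
Defaults generate amino-acid-changing edits only — the case homology
prediction is designed for and the regime the self-prediction invariant
tests (silent edits are invisible to protein-level comparison by
construction, which is why predictions on real data are always incomplete
for third-position events); a flag re-enables silent edits for
context-statistics fixtures. Generated editomes are intronless and far
smaller than real organelle genomes, so passing tests demonstrate
correctness of the bookkeeping and scoring, not recall on real editomes
with introns, trans-splicing or RNA-seq noise. Problem sizes throughout the
test-suite and acceptance script (2–3 genes of ≤80 codons, scan sequences
≤1 kb) were chosen as the smallest instances that still exercise every code
path; all published worked-example quantities are desk-scale and exact at
these sizes.

## Factor catalogue

Factor records (id, name, species, organelle, target site labels, repeat
count, C-terminal domains, protein reference, publications) live in flat
JSON; queries combine per-field verdicts with AND/OR, values matching
case-insensitively as substrings or globs. Gene-name synonymy (e.g. the
independently disrupted ccmF reading frames) is a symmetric-closure synonym
map consulted in both query and crosslink. Crosslinking attaches
`/db_xref="EdiFacts:<id>"` to every annotated site whose label matches a
factor target (all ids on ambiguity) and is idempotent. The packaged demo
store contains the two Physcomitrella patens ccmFC factors (ids 44/45,
PPR_71/PPR_65); its citation fields are synthetic placeholders.

## Known limitations

- Prediction is protein-homology based: silent edits and edits in
  non-coding regions are out of reach of the BLASTX-like mode (the cDNA
  mode catches them).
- The internal aligner is a plain local protein aligner, not a BLAST
  reimplementation: no E-values, and its score floor is a documented
  default rather than a calibrated statistic.
- The scanner attaches no p-value/FDR model to hits; ranking is by score
  only.
- Alignment mode assumes rows are in-frame CDS of a single gene.
- No live database fetching; all inputs are local files.
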
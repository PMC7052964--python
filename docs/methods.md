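# Methods

This note documents the models and procedures brettkit implements, the
choices made where the underlying methods are underspecified, and what
the synthetic-data generators do and do not emulate.

## Coordinate conventions

Every interval inside the package is 0-based, half-open. The
`show-coords` dialect (1-based inclusive, reverse strand written as a
descending query interval) and VCF (1-based POS) are converted at the
I/O boundary only. A reverse-orientation alignment record stores an
ascending query interval plus an explicit orientation flag.

## Synteny blocks

**Windowing.** Each contig is tiled with windows of `window_size`
(default 20 000 bp) every `step_size` (default 10 000 bp): starts run
0, step, 2·step, … while start < contig length, each window ending at
`min(start + window_size, length)`. A final truncated window shorter
than one step is merged into its predecessor, so no window shorter than
a step exists unless the whole contig is that short. A terminal window
of length exactly one step is kept.

**Pairing.** Each alignment's overlap with a reference window is
projected linearly onto the alignment's query interval (mirrored for
reverse orientation) and attributed to the query windows it intersects.
Per (reference window, query window, orientation) triple the pairing
accumulates: the summed projected overlap in query bp (`support_bp`);
the support-weighted mean aligned position in each genome (the
*anchors*); and the span of aligned positions in each genome (the
*support intervals*). Triples with support below `min_support_bp`
(default 2 000 bp, 10% of a window) are discarded — this suppresses
spurious pairs from short repeat alignments and is configurable.

**Concordance and merging.** Two pairs are concordant iff they share
reference contig, query contig and orientation; their support intervals
on both genomes overlap or lie within `max_gap_windows · step_size` of
each other; their diagonals agree within `diag_tolerance_bp` (default
one step), where a pair's diagonal is `qry_anchor − ref_anchor` for
forward pairs and `qry_anchor + ref_anchor` for reverse pairs; and the
anchors progress in the direction the orientation implies. Maximal sets
of transitively concordant pairs (connected components of the relation)
merge into one block spanning the union of their windows.

Two refinements beyond the obvious "overlapping or adjacent windows"
reading proved necessary. First, adjacency is measured on aligned
support, not window footprints: a 20 kb window can reach far past a
breakpoint with more than `min_support_bp` of spill, and footprint
adjacency lets chains walk across rearrangement junctions. Second, the
diagonal test separates chains that are window-adjacent on both genomes
but belong to different collinear segments — without it, a nested
inversion whose forward middle segment is displaced by less than a
window merges with its flanks. Along a perfectly collinear diagonal all
pair diagonals are equal, so the default tolerance of one step is
generous; it mainly absorbs indel drift in real alignments.

**Trimming.** After merging, reference-interval overlaps between blocks
are resolved: repeatedly, the first overlapping pair of blocks in
reference-sorted order is found and the block with smaller `support_bp`
loses the overlap (ties go against the block later in reference order);
a loser that starts before the winner keeps its lower-coordinate part,
otherwise its start moves to the winner's end. Zero-length blocks are
dropped. Processing exactly one overlap per scan makes the fixpoint
canonical. Trimming acts on the reference side only — the output is
reference-anchored, as in the Circos-style plots the blocks feed — so
query-side overlaps between blocks are permitted. A consequence worth
knowing: a genuine segment close to the window size can be trimmed away
entirely when both neighbours out-support it, so block counts at this
resolution are a lower bound on segment counts.

**Resolution.** With 20 kb windows and 2 kb minimum support, segments
much below ~20 kb are unreliable; the synthetic generator therefore
enforces a minimum segment length (default 20 kb) between breakpoints.

## ANI

Pairwise identity over an aligned FASTA: for each sequence pair,
`100 · matches / comparable_sites`, where comparable sites are columns
in which both sequences carry an unambiguous A/C/G/T. Gap and N columns
are excluded pairwise, not alignment-wide — whether the original
estimator treated gap-vs-base as a mismatch is not documented, so the
exclusion rule is this package's normative choice. Pairs with no
comparable column are reported missing (NaN). Outputs print to one
decimal; full precision is kept internally.

## Expansion screen and GO enrichment

The expansion statistic for species *s* in orthogroup *g* is
`count(g, s) / mean(count(g, ·))`, the mean taken over a configurable
averaging set that defaults to every species in the table (the
alternative reading — averaging over the focal clade only — is
expressible via `averaging_species`). Groups with zero mean are
skipped; ratio ≥ 2 flags an expansion. Note the mean includes the focal
cell, so on an all-ones 5-species background the smallest flaggable
count is 3, not 2.

Enrichment uses the upper-tail hypergeometric probability
P(X ≥ k) for k study hits of a term among n study genes, with K term
carriers in the N-gene population (scipy's `hypergeom.sf`; exact to
better than 10 significant digits in the tested range). The term
universe is the set of terms with at least one population annotation;
only terms with at least one study hit are tested, and the Bonferroni
multiplier is the number of tested terms. Term assignment is flat — no
propagation to GO ancestors — keeping the package free of an ontology
dependency.

## Alien Index

`AI = ln(e_self + c) − ln(e_alien + c)` with pseudo-count `c = 1e-200`
and a missing lineage substituted with E = 1, where `e_self`/`e_alien`
are the smallest E-values among self- and alien-lineage hits after
dropping subjects matching an `exclude_taxa` list (a substring match on
subject identifiers; no taxonomy service is consulted). Candidates are
flagged at AI **strictly** greater than 20. The exact variant (log
base, pseudo-count, missing-hit substitution) follows the commonly used
definition; with these constants the attainable score range is
±460.5 (= 200·ln 10), consistent with reported fungal HGT scores
≤ ~140. Subjects absent from the lineage map are an error by default
(silently dropping them would bias AI); an explicit drop mode exists.

## LOH classification

SNP tracks keep only single-base REF/ALT records passing the configured
VCF FILTER values. Densities are SNPs per kb over windows (default
10 kb non-overlapping for the density track; the window size is a
display choice, as contig-level sums are window-invariant).
Classification is per contig by default — LOH calls in such genomes are
made on whole contigs — with a threshold of 0.5 SNPs/kb: the two
observed density regimes sit roughly two orders of magnitude apart
(~0.035 vs ~3.2 SNPs/kb), so any threshold between them separates the
regimes and the precise value is uncritical. The genome summary reports
aggregate per-class densities (total SNPs over total bp — not the mean
of per-contig densities) and the homozygous bp fraction.

## Synthetic data generators

All generators are pure functions of a seed and their parameters, using
one named NumPy generator per call; no global RNG state.

- **Rearranged pairs**: reference contigs are i.i.d. uniform ACGT; the
  query genome is the reference with sampled translocations (applied
  first) and inversions. Every new breakpoint must land at least
  `min_segment` (default 20 kb, window-resolvable) from every existing
  breakpoint, with bounded rejection retries — an unplaceable event is
  an error, which with the default minimum makes three events on a
  single 200 kb contig effectively infeasible (an inversion needs a
  clean 2·`min_segment` gap); dense-event test families use a smaller
  minimum instead. The truth segment map tiles both genomes and
  transcribes directly into perfect alignment records, standing in for
  a whole-genome aligner.
- **SNP mosaics**: per planned region, Poisson(density · length / 1000)
  SNPs placed uniformly without replacement; regions must tile each
  contig.
- **BLAST tables**: each protein receives hits in both lineages, the
  favoured lineage drawn from a strong log10 E-value range (default
  −120…−40) and the other from a weak range (−4…0); planted HGT
  proteins have the two swapped. Truth labels and the subject→lineage
  map are returned with the table.
- **Count tables**: all-ones (or shifted-Poisson) background with
  planted cells set exactly.
- **Codon alignments**: independent leaves of a star tree around a
  random ancestor, the per-leaf substitution rate solved from
  `(1−m)² + m²/3 = t` so every leaf pair's expected identity equals the
  target (valid down to the 0.25 unrelated-sequence floor); optional
  uniform gap injection.

What these generators deliberately do not emulate: sequence evolution
(no substitution model, no indels in genomes), repeat structure,
alignment error, assembly artefacts, or E-value dependence on database
composition. Passing tests therefore demonstrate the correctness of the
algorithms against known truth under clean conditions — not robustness
to aligner noise or repeat-induced spurious alignments, which on real
genomes are mitigated by the `min_support_bp` threshold and by the
sensitive-alignment parameters documented for MUMmer
(`-b 500 -c 40 -d 0.5 -g 200 -l 12`) but are not exercised here.

## Problem sizes and determinism

The test-suite families use genomes of 80–200 kb per contig with up to
three planted events, 1000 nested event transitions for the
monotonicity property, 1000 replicate SNP mosaics on 100–250 kb
contigs, 100 simulated proteomes for the HGT screen, and 3000-codon
alignments — sizes at which the brute-force oracles remain exact and
the whole suite runs in seconds. `scripts/acceptance.py` scales the LOH
mosaic up to the 14.3 Mb diploid-genome geometry (15% homozygous bp) to
recover the per-class densities at realistic magnitudes. Identical
seeds give byte-identical outputs throughout.

## Known limitations

- Block counts depend on window geometry; sub-window segments are
  invisible and near-window segments can be lost to trimming.
- Query-side block overlaps are not resolved (reference-anchored
  design).
- The expansion ratio's denominator includes the focal species, which
  damps ratios for small species sets.
- GO enrichment without DAG propagation undercounts broad terms.
- `exclude_taxa` is a string match, not a taxonomy lookup.
- The pipeline does not run aligners, BLAST or variant callers; it
  consumes their outputs.
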
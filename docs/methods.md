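# Methods

## Data model and coordinate convention

Every parser normalises into a single record shape: 0-based, half-open
intervals on both query and target, with query coordinates always on the
forward strand of the query and a separate strand flag (the PAF
convention). PAF and PSL are native; SAM, BLAST tabular and MUMmer
output are 1-based inclusive and converted on ingest; BLAST subject
intervals with `sstart > send` and MUMmer query intervals with `E2 < S2`
are normalised ascending with strand set to reverse. Committing to one
convention at the parser boundary removes an entire class of off-by-one
bugs from everything downstream, which is why validation (interval within
sequence bounds, start < end) happens at record construction and a parser
can only ever return valid records or raise a line-numbered error.

Format-specific decisions:

* **SAM.** Unmapped (0x4) and secondary (0x100) records are skipped;
  supplementary records (0x800) are kept, because a chimeric read aligned
  by minimap2/BWA appears as one primary plus one supplementary record
  and dropping either would hide exactly the signal the chimera rule
  needs, while secondaries would double-count loci. Query intervals are
  derived from the CIGAR: clips define the offsets, and both soft and
  hard clips count toward the query length so that the split pieces of
  one read agree on its length across records. For flag 0x10 the
  stored-frame interval [s, e) of a length-*L* read is reflected to
  forward frame as [L−e, L−s). Target lengths come from `@SQ` headers
  when present, else 0 ("unknown").
* **BLAST tabular.** outfmt 6 does not carry the query length. Optional
  columns 13–14 are read as qlen/slen; without them the query length
  falls back to the maximum observed `qend` per query (a buffered fixup
  after one pass) and the records are flagged approximate, since chimera
  fractions computed on an underestimated length overstate coverage.
* **MUMmer.** `show-coords` input must be the `-l -T` tabular dialect;
  the fixed-width pretty dialect has no unambiguous column splitting.
  `show-tiling` rows carry no query coordinates at all, so the query
  interval is set to the whole contig and flagged approximate — tiling
  input is fine for coverage-style diagrams but not a good basis for
  chimera calls.

## Length filter

Alignments spanning less than a fraction *f* of their query are
discarded before anything else (default *f* = 0.01); the comparison is
`span ≥ f·L`, so an exact 1% alignment survives. The filter is
idempotent and order-preserving. It runs before chimera detection and
coverage computation, which makes the "exactly two alignments" clause of
the chimera rule robust to short spurious hits.

## Chimera rule

Defaults: combined coverage ≥ 0.90 of the query, each piece ≥ 0.10
(both adjustable; validated so that 2·m ≤ c ≤ 1 and 0 < m ≤ 0.5).
Interpretation choices where the rule's wording leaves room:

* "Exactly two" is literal: a query with three surviving alignments is
  never called, even if two dominate. The 1% filter is what keeps this
  from being brittle in practice.
* Overlap means intersection length > 0 on the query; abutting intervals
  qualify, with the join at the shared boundary.
* Two alignments to the *same* target must also have disjoint target
  intervals ("different sections"). Any positive separation qualifies —
  so a read spanning the artificial start/end junction of a circular
  replicon (chloroplast, mitochondrion) represented as linear sequence
  *is* reported. `detect_chimeras(..., exclude_targets=[...])` (CLI
  `--exclude-targets`) mechanises the exclusion of such references; it is
  off by default because whether a target is circular is knowledge the
  caller has and the alignments do not.
* The join position is ⌊(left end + right start)/2⌋ — the floor of the
  unaligned-gap midpoint; with exact alignments the true junction lies in
  that gap, so the error is at most half the gap width.

Detection output is sorted by query name so runs are deterministic
regardless of input order. The report is four tab-separated columns
(query, join, left target, right target), no header.

## Read splitting

A read named in a call is replaced in-stream by `<name>_left` = [0,
join) and `<name>_right` = [join, length), with FASTQ qualities sliced
in register; other reads pass through untouched and total bases are
conserved. A call naming an absent read warns and is skipped (reports
are often computed on a superset of the reads at hand); a join on or
outside a read's boundary is an error, because it indicates the report
and the read file disagree about the read. FASTA/FASTQ, plain or
gzipped, via Biopython.

## Coverage

A bin counts the (per-query deduplicated) alignments intersecting it by
at least one base — no fractional weighting. When one query has
overlapping alignments, the largest is kept and overlapping ones
discarded: greedy, ordered by target-span length descending with ties
broken by input order, overlap tested per target on the target axis
(the axis being binned). Counting surviving alignments rather than
distinct queries matters only for queries aligning to several disjoint
loci, which arguably should count per locus.

Defaults: 10,000 bins for the square coverage map (a 100×100 grid),
1,000 for the long bar and for genome coverage. The genome coverage
diagram uses one shared bin size, ⌈total length / total bins⌉, so every
cell spans the same number of bases across chromosomes.

## Diagrams and rendering

Layouts emit backend-neutral draw commands (line, rectangle, text,
polygon, with fill/stroke/gradient styling and a semantic `role` tag) on
a fixed 1000-unit-wide canvas; SVG and TikZ drawers serialise them with
fixed two-decimal coordinate formatting, so output is byte-deterministic.
Choices the figures do not pin down, made here once:

* Orientation/position shading: a horizontal gradient across each
  alignment rectangle from a 65%-whitened tint of the target colour at
  the target-start side to the full colour at the target-end side,
  direction reversed for reverse strand.
* Target colours: a 12-colour palette indexed by order of first
  appearance, wrapping; a swatch legend is emitted per section.
* Heat scale: linear white→red, normalised to the per-diagram maximum
  (jointly over all targets for genome coverage); an all-zero track
  renders in the zero colour rather than dividing by zero.
* Query lines that would run off the canvas (long query, short target)
  are clipped at the canvas edge and capped with a small arrow head.
* Contig-alignment sections keep the ten longest alignments by query
  span, ties by input order.

The CLI writes one file per target (alignment, coverageMap) or per query
(contigAlignment), and a single file for genomeCoverage, always to a
temporary name renamed atomically, so a failed run leaves no partial
file under a final name.

## Synthetic data generator

The generator emulates a read-to-reference alignment experiment with a
known answer: uniform-random reference sequences; reads copied from them
(reverse-complemented on reverse strand); a chosen fraction of planted
chimeras built by concatenating segments from two distinct references —
each ≥ 12% of the read, combined ≥ 92%, separated by ≤ 8% of random
junk — so every planted read satisfies the default thresholds with
margin, and every unplanted read (one full-length alignment, plus
optional spurious hits strictly under 1% of the read) violates them.
Alignments are emitted directly from read provenance rather than
recomputed by an aligner, and test serialisers write them as PAF, SAM,
extended BLAST6 and PSL for parser round-trips.

What this does **not** emulate: sequencing errors and the resulting
ragged alignment endpoints, split or partial alignments of non-chimeric
reads, repeats and paralogy, uneven coverage. Perfect recall/precision
on this fixture therefore validates the rule's implementation, not its
field performance on noisy reads, where alignment-endpoint slop moves
real reads across the 90%/10% thresholds in both directions.

Acceptance-scale runs use 5000 reads (10% chimeric) for detection
scoring and a few hundred reads for conservation and rendering checks;
these sizes give single-digit-second runs while exercising every code
path at non-trivial multiplicity.

## Known limitations

* BAM/CRAM, MAF, delta and chain formats are out of scope; SAM must be
  text.
* Base-level detail (CIGAR beyond span computation, MAPQ, scores) is not
  retained.
* A query whose two true pieces are accompanied by a third surviving
  alignment is never called (literal "exactly two").
* Visual constants (fonts, margins, palette) are this package's own;
  diagrams are matched structurally, not pixel-wise, by the tests.
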
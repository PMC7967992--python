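# alnviz

Pairwise-alignment visualisation and chimera detection for long reads and
assemblies.

When long reads (nanopore in particular) or assembled contigs are aligned
to a reference genome or gene set, the aligner's tab-separated output is
easy for scripts to consume but hard for a person to reason about. alnviz
parses alignments from five common formats — PAF (minimap2), SAM,
BLAST tabular (outfmt 6), PSL (BLAT), and MUMmer `show-coords`/
`show-tiling` output — into one normalised record model, renders four
types of publication-quality vector diagram (SVG or TikZ), and flags
**chimeric reads**: single sequenced molecules that artificially join two
unrelated genomic fragments (a library-ligation or in-pore basecalling
artefact). Splitting flagged reads at the estimated junction before
assembly can noticeably improve assembly contiguity.

## The chimera rule

All coordinates are 0-based, half-open, with query intervals expressed on
the forward strand of the query. A query *q* of length *L* with filtered
alignments {a₁, …, aₙ} is called chimeric iff:

1. *n* = 2 — exactly two alignments survive the length filter;
2. their query intervals are disjoint (abutting is allowed);
3. they hit different targets, or disjoint sections of the same target;
4. |a₁| + |a₂| ≥ c·L (combined coverage, default c = 0.90);
5. min(|a₁|, |a₂|) ≥ m·L (each piece, default m = 0.10),

where |aᵢ| is the aligned span on the query. The estimated join position
is the midpoint of the unaligned gap, ⌊(end(a₁) + start(a₂))/2⌋. Before
detection, alignments spanning less than 1% of their query (default,
adjustable) are discarded as noise.

## Diagrams

* **alignment** — per target: a red bar for the target, one rectangle per
  alignment at its target interval, with a line through each rectangle
  showing the full query extent and position.
* **contigAlignment** — per query: the query as an outline box containing
  its ten longest alignments at their query intervals, colour-coded by
  target and gradient-shaded to encode target position and orientation;
  chimeric queries are marked `C`.
* **coverageMap** — per target: bin counts of aligned queries rendered as
  a heat map, either a wrapped square or a long bar.
* **genomeCoverage** — one heat map over all targets in order at a single
  shared bin size (constant bases per cell).

## Worked example

The package ships a deterministic synthetic-data generator (used by the
test suite), so the whole pipeline runs without external data:

```python
from alnviz.fixtures import FixtureSpec, generate, serialize

fx = generate(FixtureSpec(seed=11, n_targets=3, n_reads=50, chimera_fraction=0.1))
with open("demo.paf", "w") as fh:
    serialize(fx.alignments, "paf", fh)
```

```sh
alnviz -inputfmt paf -type contigAlignment -printChimeras \
       -in demo.paf -outdir out -out demo
```

prints

```
[alnviz] INFO parsed 64 alignments (50 queries, 3 targets) from demo.paf
[alnviz] INFO length filter (0.01 of query) kept 55 of 64 alignments
[alnviz] INFO chimera rule flagged 5 of 50 queries
[alnviz] INFO wrote chimera report with 5 calls
```

Of the 64 alignments, 9 are spurious sub-1% hits removed by the filter;
the 5 flagged queries are exactly the 5 planted chimeras (0.1 × 50). One
SVG per query lands in `out/`, and `out/demo_chimeras.txt` holds the
4-column report — query name, approximate join position, and the two
target names:

```
read00007	1832	ref3	ref1
read00014	5523	ref1	ref3
read00016	1243	ref1	ref3
read00020	2351	ref3	ref2
read00025	6137	ref3	ref1
```

Splitting the flagged reads at those positions for re-assembly:

```sh
alnviz split -in reads.fastq -report out/demo_chimeras.txt -out split.fastq
```

Each flagged read is replaced by `<name>_left` and `<name>_right`; total
bases are conserved and untouched reads pass through unchanged.

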
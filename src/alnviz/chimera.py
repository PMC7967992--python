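"""Chimeric-query detection, reporting and read splitting.

A chimeric read is a single sequenced molecule artificially joining two
distinct genomic fragments (a ligation or in-pore basecalling artefact).
Against a reference, such a read shows up as two disjoint alignments to
unrelated loci.  The classification rule used here is purely geometric:

a query is called chimeric iff, after length filtering, it has

* exactly two alignments,
* whose query intervals do not overlap,
* to different targets, or to non-overlapping sections of one target,
* together covering at least ``min_total_coverage`` (default 90%) of the
  query, and
* each covering at least ``min_each_fraction`` (default 10%) of the query.

The estimated join position is the midpoint of the unaligned gap between
the two alignments.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .model import AlignmentRecord, AlignmentSet, group_by

__all__ = [
    "ChimeraParams",
    "ChimeraCall",
    "SeqRecord",
    "classify_query",
    "detect_chimeras",
    "write_chimera_report",
    "read_chimera_report",
    "split_reads",
    "read_seq_file",
    "write_seq_file",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChimeraParams:
    """Thresholds of the chimera rule, as fractions of the query length."""

    min_total_coverage: float = 0.90
    min_each_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.min_each_fraction <= 0.5):
            raise ValueError("min_each_fraction must lie in (0, 0.5]")
        if not (2 * self.min_each_fraction <= self.min_total_coverage <= 1.0):
            raise ValueError(
                "min_total_coverage must lie in [2 * min_each_fraction, 1]"
            )


@dataclass(frozen=True)
class ChimeraCall:
    """A flagged query, its two supporting alignments, and the join estimate."""

    query_name: str
    join_position: int
    left_alignment: AlignmentRecord
    right_alignment: AlignmentRecord

    def __post_init__(self) -> None:
        if not (self.left_alignment.query_start < self.right_alignment.query_start):
            raise ValueError("left/right alignments out of order on the query")
        if not (
            self.left_alignment.query_end
            <= self.join_position
            <= self.right_alignment.query_start
        ):
            raise ValueError("join position outside the inter-alignment gap")

    @property
    def same_target(self) -> bool:
        return self.left_alignment.target_name == self.right_alignment.target_name


def classify_query(
    records_of_one_query: Sequence[AlignmentRecord],
    params: ChimeraParams = ChimeraParams(),
) -> ChimeraCall | None:
    """Apply the chimera rule to the (post-filter) alignments of one query.

    Returns a :class:`ChimeraCall` or ``None``.  Overlap means a positive
    intersection length, so abutting query intervals still qualify, with
    the join at the shared boundary.
    """
    lengths = {rec.query_length for rec in records_of_one_query}
    names = {rec.query_name for rec in records_of_one_query}
    if len(names) > 1:
        raise ValueError(f"records of more than one query: {sorted(names)}")
    if len(lengths) > 1:
        raise ValueError(
            f"records of query {names.pop()!r} disagree on query_length: {sorted(lengths)}"
        )
    if len(records_of_one_query) != 2:
        return None
    left, right = sorted(records_of_one_query, key=lambda r: (r.query_start, r.query_end))
    if left.query_start == right.query_start:
        return None  # identical starts necessarily overlap
    if left.query_end > right.query_start:
        return None  # query intervals overlap
    if left.target_name == right.target_name:
        t1, t2 = sorted([left, right], key=lambda r: r.target_start)
        if t1.target_end > t2.target_start:
            return None  # same section of the same target
    qlen = left.query_length
    if left.query_span + right.query_span < params.min_total_coverage * qlen:
        return None
    if min(left.query_span, right.query_span) < params.min_each_fraction * qlen:
        return None
    join = (left.query_end + right.query_start) // 2
    return ChimeraCall(
        query_name=left.query_name,
        join_position=join,
        left_alignment=left,
        right_alignment=right,
    )


def detect_chimeras(
    alignments: AlignmentSet,
    params: ChimeraParams = ChimeraParams(),
    exclude_targets: Iterable[str] = (),
) -> list[ChimeraCall]:
    """Classify every query in an (already length-filtered) set.

    ``exclude_targets`` drops same-target calls on the named references;
    this mechanises the manual exclusion of joins across a circular
    sequence (mitochondrion, chloroplast) represented linearly.  Output is
    sorted by query name for determinism.
    """
    excluded = set(exclude_targets)
    calls = []
    for name, group in group_by(alignments, "query").items():
        call = classify_query(group, params)
        if call is None:
            continue
        if call.same_target and call.left_alignment.target_name in excluded:
            continue
        calls.append(call)
    calls.sort(key=lambda c: c.query_name)
    return calls


def write_chimera_report(calls: Sequence[ChimeraCall], sink: IO[str]) -> None:
    """Write the 4-column tab-separated chimera report.

    Columns: query name, approximate join position (midway between the two
    alignments), target of the left alignment, target of the right
    alignment.  No header.
    """
    for call in calls:
        sink.write(
            f"{call.query_name}\t{call.join_position}\t"
            f"{call.left_alignment.target_name}\t{call.right_alignment.target_name}\n"
        )


def read_chimera_report(source: IO[str]) -> list[tuple[str, int]]:
    """Read (query name, join position) pairs back from a report."""
    out = []
    for line in source:
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed chimera report line: {line!r}")
        out.append((fields[0], int(fields[1])))
    return out


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence with optional per-base qualities (FASTQ)."""

    name: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.name}: quality string length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def split_reads(
    reads: Iterable[SeqRecord],
    calls: Sequence[ChimeraCall] | Sequence[tuple[str, int]],
) -> Iterator[SeqRecord]:
    """Split each read named in ``calls`` at its join position.

    A named read is replaced, in place in the stream, by its prefix
    ``<name>_left`` = [0, join) and suffix ``<name>_right`` = [join, end);
    qualities are split in register.  All other reads pass through
    unchanged.  A call naming a read absent from the input produces a
    warning at the end of iteration; a join position on or outside a
    read's boundary is an error.
    """
    joins: dict[str, int] = {}
    for call in calls:
        if isinstance(call, ChimeraCall):
            joins[call.query_name] = call.join_position
        else:
            name, pos = call
            joins[name] = int(pos)
    seen: set[str] = set()
    for read in reads:
        if read.name not in joins:
            yield read
            continue
        seen.add(read.name)
        join = joins[read.name]
        if not (0 < join < len(read)):
            raise ValueError(
                f"join position {join} outside read {read.name!r} of length {len(read)}"
            )
        for suffix, lo, hi in (("_left", 0, join), ("_right", join, len(read))):
            yield SeqRecord(
                name=read.name + suffix,
                sequence=read.sequence[lo:hi],
                qualities=None if read.qualities is None else read.qualities[lo:hi],
            )
    for missing in set(joins) - seen:
        logger.warning("chimera call for read %r not found in input; skipped", missing)


# --- FASTA/FASTQ IO (gzip-transparent, Biopython-backed) -------------------


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode, encoding="utf-8")


def sequence_format(path) -> str:
    """Infer 'fasta' or 'fastq' from a file name (gzip suffix transparent)."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def read_seq_file(path, fmt: str | None = None) -> Iterator[SeqRecord]:
    """Stream reads from a FASTA/FASTQ file, plain or gzipped."""
    fmt = fmt or sequence_format(path)
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            yield SeqRecord(
                name=rec.id,
                sequence=str(rec.seq),
                qualities=None
                if quals is None
                else "".join(chr(q + 33) for q in quals),
            )


def write_seq_file(reads: Iterable[SeqRecord], path, fmt: str | None = None) -> int:
    """Write reads as FASTA/FASTQ (by ``fmt`` or file name); returns count."""
    fmt = fmt or sequence_format(path)
    n = 0
    with _open_text(path, "w") as handle:
        for read in reads:
            rec = _BioSeqRecord(Seq(read.sequence), id=read.name, description="")
            if fmt == "fastq":
                quals = read.qualities or "I" * len(read.sequence)
                rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
            SeqIO.write(rec, handle, fmt)
            n += 1
    return n
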
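"""Binned coverage of target sequences.

Each target is divided into fixed-width positional bins; a bin's count is
incremented once for every (per-query deduplicated) alignment that
intersects it by at least one base.  These tracks feed the per-target
coverage map and the whole-genome coverage diagram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from .model import AlignmentRecord, AlignmentSet, dedup_overlapping, group_by

__all__ = [
    "CoverageTrack",
    "GenomeCoverage",
    "compute_track",
    "compute_genome_coverage",
    "dedup_per_query",
    "write_tracks_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageTrack:
    """Bin counts for one target at a fixed bin size."""

    target_name: str
    target_length: int
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        expected = math.ceil(self.target_length / self.bin_size)
        if len(self.counts) != expected:
            raise ValueError(
                f"{self.target_name}: {len(self.counts)} bins, expected {expected}"
            )
        if (np.asarray(self.counts) < 0).any():
            raise ValueError(f"{self.target_name}: negative bin count")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def max_count(self) -> int:
        return int(self.counts.max()) if len(self.counts) else 0


@dataclass(frozen=True)
class GenomeCoverage:
    """Ordered per-target tracks sharing one bin size, with bin offsets."""

    tracks: tuple[CoverageTrack, ...]
    boundaries: tuple[int, ...]  # cumulative bin offset of each track (plus total)

    def __post_init__(self) -> None:
        sizes = {t.bin_size for t in self.tracks}
        if len(sizes) > 1:
            raise ValueError(f"tracks disagree on bin_size: {sorted(sizes)}")

    @property
    def bin_size(self) -> int:
        return self.tracks[0].bin_size if self.tracks else 0

    @property
    def max_count(self) -> int:
        return max((t.max_count for t in self.tracks), default=0)


def dedup_per_query(alignments: AlignmentSet) -> AlignmentSet:
    """Apply the largest-alignment overlap resolution query by query."""
    kept: list[AlignmentRecord] = []
    for group in group_by(alignments, "query").values():
        kept.extend(dedup_overlapping(group))
    return AlignmentSet(kept)


def compute_track(
    alignments_on_target: Sequence[AlignmentRecord],
    target_name: str,
    target_length: int,
    bin_size: int,
) -> CoverageTrack:
    """Count, per bin, the alignments intersecting it by >= 1 base.

    ``alignments_on_target`` should already be per-query deduplicated
    (see :func:`dedup_per_query`).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if target_length < 1:
        raise ValueError(f"{target_name}: cannot bin a target of unknown length")
    n_bins = math.ceil(target_length / bin_size)
    counts = np.zeros(n_bins, dtype=np.int64)
    for rec in alignments_on_target:
        if rec.target_end > target_length:
            raise ValueError(
                f"{rec.query_name}: target_end {rec.target_end} exceeds "
                f"{target_name} length {target_length}"
            )
        first = rec.target_start // bin_size
        last = (rec.target_end - 1) // bin_size
        counts[first : last + 1] += 1
    return CoverageTrack(
        target_name=target_name,
        target_length=target_length,
        bin_size=bin_size,
        counts=counts,
    )


def compute_genome_coverage(
    alignments: AlignmentSet,
    target_order: Sequence[tuple[str, int]],
    total_bins: int,
) -> GenomeCoverage:
    """Cover all targets at one shared bin size.

    ``bin_size = ceil(total target length / total_bins)``, identical for
    every track, so every bin spans the same number of bases and maps to a
    constant-size cell in the genome coverage diagram.  Alignments to
    targets absent from ``target_order`` are skipped with a warning.
    """
    if total_bins < len(target_order):
        raise ValueError("total_bins must be >= number of targets")
    total_length = sum(length for _, length in target_order)
    if total_length <= 0:
        return GenomeCoverage(tracks=(), boundaries=(0,))
    bin_size = math.ceil(total_length / total_bins)
    known = {name for name, _ in target_order}
    by_target = group_by(alignments, "target")
    for name in by_target:
        if name not in known:
            logger.warning("alignments to unknown target %r skipped", name)
    tracks = []
    boundaries = [0]
    for name, length in target_order:
        track = compute_track(by_target.get(name, []), name, length, bin_size)
        tracks.append(track)
        boundaries.append(boundaries[-1] + track.n_bins)
    return GenomeCoverage(tracks=tuple(tracks), boundaries=tuple(boundaries))


def write_tracks_tsv(tracks: Sequence[CoverageTrack], sink: IO[str]) -> None:
    """Export tracks as (target, bin index, count) rows for external plotting."""
    sink.write("target\tbin\tcount\n")
    for track in tracks:
        for i, c in enumerate(track.counts):
            sink.write(f"{track.target_name}\t{i}\t{int(c)}\n")
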
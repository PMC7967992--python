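"""Canonical alignment data model and alignment-level filters.

Every parser in :mod:`alnviz.parsers` normalises its input into
:class:`AlignmentRecord` objects using a single coordinate convention:
0-based, half-open intervals, with query coordinates always expressed on
the forward strand of the query (the PAF convention).  Downstream stages
(chimera detection, coverage, diagrams) only ever see this one shape.
"""

from __future__ import annotations

import enum
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Strand",
    "AlignmentRecord",
    "AlignmentSet",
    "filter_by_min_length",
    "group_by",
    "dedup_overlapping",
]


class Strand(enum.Enum):
    """Orientation of the query relative to the target."""

    FORWARD = "+"
    REVERSE = "-"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AlignmentRecord:
    """One normalised pairwise alignment.

    Intervals are 0-based half-open.  ``query_start``/``query_end`` are on
    the forward strand of the query regardless of :attr:`strand`.  A
    ``target_length`` of 0 means the length was not available in the input
    format.  ``approximate`` marks records whose query length or interval
    was inferred rather than read from the file (BLAST tabular without a
    qlen column, tiling rows).
    """

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    strand: Strand = Strand.FORWARD
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.query_length <= 0:
            raise ValueError(f"{self.query_name}: query_length must be > 0")
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"{self.query_name}: bad query interval "
                f"[{self.query_start},{self.query_end}) for length {self.query_length}"
            )
        if self.target_length < 0:
            raise ValueError(f"{self.target_name}: target_length must be >= 0")
        upper = self.target_length if self.target_length > 0 else None
        if self.target_start < 0 or self.target_start >= self.target_end:
            raise ValueError(
                f"{self.query_name}->{self.target_name}: bad target interval "
                f"[{self.target_start},{self.target_end})"
            )
        if upper is not None and self.target_end > upper:
            raise ValueError(
                f"{self.query_name}->{self.target_name}: target interval "
                f"[{self.target_start},{self.target_end}) exceeds length {upper}"
            )

    @property
    def query_span(self) -> int:
        """Length of the aligned span on the query."""
        return self.query_end - self.query_start

    # alias used by the original interface vocabulary
    @property
    def alignment_block_length(self) -> int:
        return self.query_span

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


class AlignmentSet:
    """An ordered collection of :class:`AlignmentRecord` with name indices.

    Iteration order is the input file order.  ``query_index`` and
    ``target_index`` map names to record positions and together form a
    partition of the records.
    """

    def __init__(self, records: Iterable[AlignmentRecord] = ()) -> None:
        self._records: list[AlignmentRecord] = list(records)
        self._query_index: OrderedDict[str, list[int]] = OrderedDict()
        self._target_index: OrderedDict[str, list[int]] = OrderedDict()
        for i, rec in enumerate(self._records):
            self._query_index.setdefault(rec.query_name, []).append(i)
            self._target_index.setdefault(rec.target_name, []).append(i)

    @property
    def records(self) -> Sequence[AlignmentRecord]:
        return tuple(self._records)

    @property
    def query_index(self) -> dict[str, list[int]]:
        return {k: list(v) for k, v in self._query_index.items()}

    @property
    def target_index(self) -> dict[str, list[int]]:
        return {k: list(v) for k, v in self._target_index.items()}

    def query_names(self) -> list[str]:
        return list(self._query_index)

    def target_names(self) -> list[str]:
        return list(self._target_index)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AlignmentRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> AlignmentRecord:
        return self._records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignmentSet):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AlignmentSet({len(self._records)} records, "
            f"{len(self._query_index)} queries, {len(self._target_index)} targets)"
        )


def filter_by_min_length(alignments: AlignmentSet, min_fraction: float) -> AlignmentSet:
    """Drop alignments spanning less than ``min_fraction`` of their query.

    A record survives iff ``query_end - query_start >= min_fraction *
    query_length``.  The default pipeline value of 0.01 removes noise
    alignments shorter than 1% of the query.  Input order is preserved and
    the input set is not modified.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in [0, 1]")
    return AlignmentSet(
        rec
        for rec in alignments
        if rec.query_span >= min_fraction * rec.query_length
    )


def group_by(alignments: AlignmentSet, axis: str) -> "OrderedDict[str, list[AlignmentRecord]]":
    """Partition records by ``axis`` ("query" or "target") name.

    Group order follows first appearance; records within a group keep
    input order.
    """
    if axis not in ("query", "target"):
        raise ValueError(f"axis must be 'query' or 'target', got {axis!r}")
    groups: OrderedDict[str, list[AlignmentRecord]] = OrderedDict()
    for rec in alignments:
        key = rec.query_name if axis == "query" else rec.target_name
        groups.setdefault(key, []).append(rec)
    return groups


def dedup_overlapping(records_of_one_query: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Resolve overlapping alignments of a single query greedily.

    Used before coverage counting: when one query has overlapping
    alignments the largest is kept and the overlapping ones are discarded.
    "Largest" means largest target span; ties are broken by input order.
    Overlap is tested on the target axis, per target.
    """
    names = {rec.query_name for rec in records_of_one_query}
    if len(names) > 1:
        raise ValueError(f"records of more than one query: {sorted(names)}")
    order = sorted(
        range(len(records_of_one_query)),
        key=lambda i: (-records_of_one_query[i].target_span, i),
    )
    accepted: list[int] = []
    for i in order:
        rec = records_of_one_query[i]
        clash = any(
            records_of_one_query[j].target_name == rec.target_name
            and records_of_one_query[j].target_start < rec.target_end
            and rec.target_start < records_of_one_query[j].target_end
            for j in accepted
        )
        if not clash:
            accepted.append(i)
    return [records_of_one_query[i] for i in sorted(accepted)]
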
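"""Parsers for the supported pairwise-alignment formats.

Each parser consumes an iterable of text lines and produces an
:class:`~alnviz.model.AlignmentSet` in the canonical convention
(0-based half-open, forward-frame query coordinates).  Coordinate
conventions per format:

========  =========================  =========================
format    native coordinates         reverse-strand encoding
========  =========================  =========================
PAF       0-based half-open          strand column, query fwd-frame
SAM       1-based POS                flag 0x10, stored read reversed
BLAST6    1-based inclusive          sstart > send
PSL       0-based half-open          strand column, qStart fwd-frame
coords    1-based inclusive          E2 < S2 (query columns)
tiling    1-based inclusive          orientation column
========  =========================  =========================
"""

from __future__ import annotations

import logging
import re
from typing import IO, Iterable, Union

from .model import AlignmentRecord, AlignmentSet, Strand

__all__ = [
    "FORMATS",
    "ParseError",
    "parse",
    "parse_paf",
    "parse_sam",
    "parse_blast_tab",
    "parse_psl",
    "parse_coords",
    "parse_tiling",
]

logger = logging.getLogger(__name__)

#: Closed enumeration of accepted -inputfmt values.
FORMATS = ("paf", "sam", "blast", "psl", "coords", "tiling")

LineSource = Union[IO[str], Iterable[str]]


class ParseError(ValueError):
    """Raised on malformed input; carries a 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None) -> None:
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def _int(value: str, what: str, line_number: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"non-integer {what}: {value!r}", line_number) from None


def _record(line_number: int, **kwargs) -> AlignmentRecord:
    try:
        return AlignmentRecord(**kwargs)
    except ValueError as exc:
        raise ParseError(str(exc), line_number) from None


def parse_paf(stream: LineSource) -> AlignmentSet:
    """Parse PAF (minimap2's pairwise alignment format).

    PAF is already in the canonical convention, so fields 1-9 are stored
    unchanged.  Lines need at least the 12 mandatory fields.
    """
    records = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"expected >= 12 tab-separated fields, got {len(fields)}", lineno)
        records.append(
            _record(
                lineno,
                query_name=fields[0],
                query_length=_int(fields[1], "query length", lineno),
                query_start=_int(fields[2], "query start", lineno),
                query_end=_int(fields[3], "query end", lineno),
                strand=Strand.REVERSE if fields[4] == "-" else Strand.FORWARD,
                target_name=fields[5],
                target_length=_int(fields[6], "target length", lineno),
                target_start=_int(fields[7], "target start", lineno),
                target_end=_int(fields[8], "target end", lineno),
            )
        )
    return AlignmentSet(records)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR op consumption: (query, target)
_CIGAR_CONSUMES = {
    "M": (True, True),
    "I": (True, False),
    "D": (False, True),
    "N": (False, True),
    "S": (True, False),
    "H": (True, False),  # hard clips count toward query_length here
    "P": (False, False),
    "=": (True, True),
    "X": (True, True),
}


def _walk_cigar(cigar: str, lineno: int) -> tuple[int, int, int, int]:
    """Return (query_length, stored_qstart, stored_qend, target_span).

    The stored query interval is in the orientation the read is stored in
    (SAM stores reverse-strand reads reverse-complemented); soft and hard
    clips define the offsets and both clip types count toward the query
    length, so split pieces of one read agree on its length.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(n + op for n, op in ops) != cigar:
        raise ParseError(f"unparseable CIGAR {cigar!r}", lineno)
    qlen = 0
    tspan = 0
    leading = 0
    trailing = 0
    seen_aligned = False
    for n_str, op in ops:
        n = int(n_str)
        cq, ct = _CIGAR_CONSUMES[op]
        if cq:
            qlen += n
        if ct:
            tspan += n
        if op in "SH":
            if seen_aligned:
                trailing += n
            else:
                leading += n
        else:
            seen_aligned = True
            trailing = 0
    return qlen, leading, qlen - trailing, tspan


def parse_sam(stream: LineSource) -> AlignmentSet:
    """Parse text SAM.

    Unmapped (0x4) and secondary (0x100) records are skipped; supplementary
    records (0x800) are kept, since split/chimeric reads manifest as
    supplementaries.  Query coordinates are derived from the CIGAR and
    re-expressed on the forward query strand for flag 0x10.  Target lengths
    come from ``@SQ`` headers when present, else 0.
    """
    records = []
    sq_lengths: dict[str, int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("@"):
            if line.startswith("@SQ"):
                name = length = None
                for tag in line.split("\t")[1:]:
                    if tag.startswith("SN:"):
                        name = tag[3:]
                    elif tag.startswith("LN:"):
                        length = _int(tag[3:], "@SQ LN", lineno)
                if name is not None and length is not None:
                    sq_lengths[name] = length
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ParseError(f"expected >= 11 SAM fields, got {len(fields)}", lineno)
        flag = _int(fields[1], "FLAG", lineno)
        if flag & 0x4 or flag & 0x100:
            continue
        cigar = fields[5]
        if cigar == "*":
            logger.warning("line %d: mapped record %s has no CIGAR; skipped", lineno, fields[0])
            continue
        pos = _int(fields[3], "POS", lineno)
        qlen, s_qs, s_qe, tspan = _walk_cigar(cigar, lineno)
        if flag & 0x10:
            strand = Strand.REVERSE
            qs, qe = qlen - s_qe, qlen - s_qs
        else:
            strand = Strand.FORWARD
            qs, qe = s_qs, s_qe
        target = fields[2]
        records.append(
            _record(
                lineno,
                query_name=fields[0],
                query_length=qlen,
                query_start=qs,
                query_end=qe,
                strand=strand,
                target_name=target,
                target_length=sq_lengths.get(target, 0),
                target_start=pos - 1,
                target_end=pos - 1 + tspan,
            )
        )
    return AlignmentSet(records)


def parse_blast_tab(stream: LineSource) -> AlignmentSet:
    """Parse BLAST tabular (outfmt 6), optionally extended with qlen/slen.

    Columns 7-10 (qstart, qend, sstart, send) are 1-based inclusive;
    ``sstart > send`` marks a reverse-strand hit and the target interval is
    normalised ascending.  Without a qlen column the query length falls
    back to the maximum qend observed for that query across the whole file
    and the records are flagged approximate.
    """
    # (lineno, kwargs) buffered so the max-qend fixup can run after one pass
    pending: list[tuple[int, dict]] = []
    max_qend: dict[str, int] = {}
    fallback_used = False
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"expected >= 12 BLAST6 columns, got {len(fields)}", lineno)
        qstart = _int(fields[6], "qstart", lineno)
        qend = _int(fields[7], "qend", lineno)
        sstart = _int(fields[8], "sstart", lineno)
        send = _int(fields[9], "send", lineno)
        if sstart > send:
            strand = Strand.REVERSE
            sstart, send = send, sstart
        else:
            strand = Strand.FORWARD
        qlen = _int(fields[12], "qlen", lineno) if len(fields) >= 13 else None
        slen = _int(fields[13], "slen", lineno) if len(fields) >= 14 else 0
        name = fields[0]
        max_qend[name] = max(max_qend.get(name, 0), qend)
        if qlen is None:
            fallback_used = True
        pending.append(
            (
                lineno,
                dict(
                    query_name=name,
                    query_length=qlen,
                    query_start=qstart - 1,
                    query_end=qend,
                    strand=strand,
                    target_name=fields[1],
                    target_length=slen,
                    target_start=sstart - 1,
                    target_end=send,
                ),
            )
        )
    if fallback_used:
        logger.warning(
            "BLAST6 input lacks a qlen column; query lengths approximated "
            "by the maximum observed qend per query"
        )
    records = []
    for lineno, kwargs in pending:
        if kwargs["query_length"] is None:
            kwargs["query_length"] = max_qend[kwargs["query_name"]]
            kwargs["approximate"] = True
        records.append(_record(lineno, **kwargs))
    return AlignmentSet(records)


_PSL_HEADER_PREFIXES = ("psLayout", "match", "-----", " ")


def parse_psl(stream: LineSource) -> AlignmentSet:
    """Parse PSL (BLAT).  The optional 5-line header block is skipped.

    PSL is 0-based half-open and qStart/qEnd are always forward-frame, so
    the nine relevant columns map directly.
    """
    records = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if any(line.startswith(p) for p in _PSL_HEADER_PREFIXES):
            continue
        fields = line.split("\t")
        if len(fields) != 21:
            raise ParseError(f"expected 21 PSL columns, got {len(fields)}", lineno)
        strand_field = fields[8]
        records.append(
            _record(
                lineno,
                query_name=fields[9],
                query_length=_int(fields[10], "qSize", lineno),
                query_start=_int(fields[11], "qStart", lineno),
                query_end=_int(fields[12], "qEnd", lineno),
                strand=Strand.REVERSE if strand_field.startswith("-") else Strand.FORWARD,
                target_name=fields[13],
                target_length=_int(fields[14], "tSize", lineno),
                target_start=_int(fields[15], "tStart", lineno),
                target_end=_int(fields[16], "tEnd", lineno),
            )
        )
    return AlignmentSet(records)


def _is_coords_header(line: str) -> bool:
    stripped = line.strip()
    return (
        not stripped
        or stripped.startswith(("=", "[", "NUCMER", "/"))
        or stripped == "NUCMER"
    )


def parse_coords(stream: LineSource) -> AlignmentSet:
    """Parse MUMmer ``show-coords -l -T`` tabular output.

    Columns are (S1, E1, S2, E2, LEN1, LEN2, %IDY, LENR, LENQ, refID,
    qryID) with the reference as target.  Coordinates are 1-based
    inclusive; ``E2 < S2`` marks a reverse-strand match and the query
    interval is normalised ascending (MUMmer reports query positions on the
    forward strand).  Banner and column-tag header lines are skipped.
    """
    records = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if _is_coords_header(line):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ParseError(f"expected >= 11 show-coords -l -T columns, got {len(fields)}", lineno)
        s1 = _int(fields[0], "S1", lineno)
        e1 = _int(fields[1], "E1", lineno)
        s2 = _int(fields[2], "S2", lineno)
        e2 = _int(fields[3], "E2", lineno)
        lenr = _int(fields[7], "LENR", lineno)
        lenq = _int(fields[8], "LENQ", lineno)
        if e2 < s2:
            strand = Strand.REVERSE
            s2, e2 = e2, s2
        else:
            strand = Strand.FORWARD
        if e1 < s1:  # defensive: some pipelines emit reversed reference too
            s1, e1 = e1, s1
        records.append(
            _record(
                lineno,
                query_name=fields[10],
                query_length=lenq,
                query_start=s2 - 1,
                query_end=e2,
                strand=strand,
                target_name=fields[9],
                target_length=lenr,
                target_start=s1 - 1,
                target_end=e1,
            )
        )
    return AlignmentSet(records)


def parse_tiling(stream: LineSource) -> AlignmentSet:
    """Parse MUMmer ``show-tiling`` default output.

    ``>`` lines name the current reference (with its length when given);
    data rows are (start, end, gap, contig length, alignment coverage,
    identity, orientation, contig ID).  Tiling rows carry no query
    coordinates, so the query interval is set to [0, contig_length) and
    flagged approximate.
    """
    records = []
    target_name: str | None = None
    target_length = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            if not parts:
                raise ParseError("reference line without a name", lineno)
            target_name = parts[0]
            target_length = 0
            if len(parts) >= 2 and parts[1].isdigit():
                target_length = int(parts[1])
            continue
        if target_name is None:
            raise ParseError("data row before any '>' reference line", lineno)
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(f"expected 8 show-tiling columns, got {len(fields)}", lineno)
        start = _int(fields[0], "start", lineno)
        end = _int(fields[1], "end", lineno)
        contig_len = _int(fields[3], "contig length", lineno)
        if end < start:
            start, end = end, start
        records.append(
            _record(
                lineno,
                query_name=fields[7],
                query_length=contig_len,
                query_start=0,
                query_end=contig_len,
                strand=Strand.REVERSE if fields[6].strip() == "-" else Strand.FORWARD,
                target_name=target_name,
                target_length=target_length,
                target_start=start - 1,
                target_end=end,
                approximate=True,
            )
        )
    return AlignmentSet(records)


_PARSERS = {
    "paf": parse_paf,
    "sam": parse_sam,
    "blast": parse_blast_tab,
    "psl": parse_psl,
    "coords": parse_coords,
    "tiling": parse_tiling,
}


def parse(path, fmt: str) -> AlignmentSet:
    """Parse ``path`` as format ``fmt`` (one of :data:`FORMATS`)."""
    if fmt not in _PARSERS:
        raise ValueError(f"unknown input format {fmt!r}; expected one of {', '.join(FORMATS)}")
    with open(path, "r", encoding="utf-8") as handle:
        return _PARSERS[fmt](handle)
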
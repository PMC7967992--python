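"""Deterministic synthetic data: references, reads, planted chimeras.

The generator builds a small reference set, draws reads from it, and
emits the alignments those reads would produce — exactly, without running
an aligner.  A chosen fraction of reads are planted chimeras: the
concatenation of segments from two distinct references, each at least 12%
of the read and together at least 92% (comfortably inside the default
detection thresholds of 10% / 90%), separated by a short unaligned junk
gap.  Spurious noise alignments shorter than 1% of the read length are
sprinkled in at a configurable rate, so the default length filter removes
exactly the noise.

Because alignments reflect true read provenance, detection results can be
scored against an exact truth set.  No sequencing-error model is applied:
the alignments are constructed, not recomputed, so base-level noise would
change nothing downstream.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import IO, Sequence

from .chimera import ChimeraCall, SeqRecord
from .model import AlignmentRecord, AlignmentSet, Strand

__all__ = ["FixtureSpec", "Fixture", "generate", "serialize"]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic read/alignment set."""

    seed: int = 0
    n_targets: int = 4
    target_length_range: tuple[int, int] = (20_000, 50_000)
    n_reads: int = 200
    read_length_range: tuple[int, int] = (2_000, 12_000)
    chimera_fraction: float = 0.10
    noise_alignment_rate: float = 0.20

    def __post_init__(self) -> None:
        for frac in (self.chimera_fraction, self.noise_alignment_rate):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        for lo, hi in (self.target_length_range, self.read_length_range):
            if lo > hi or lo <= 0:
                raise ValueError("ranges must be non-empty and positive")
        if self.chimera_fraction > 0 and self.n_targets < 2:
            raise ValueError("chimeras need at least two targets")
        if self.read_length_range[0] < 200:
            raise ValueError(
                "reads shorter than 200 bp cannot host the planted chimera "
                "geometry; raise read_length_range"
            )
        if self.target_length_range[0] < self.read_length_range[1]:
            raise ValueError("targets must be at least as long as the longest read")


@dataclass(frozen=True)
class Fixture:
    """Generated reads, their exact alignments, and the planted truth."""

    targets: dict[str, str]
    reads: tuple[SeqRecord, ...]
    alignments: AlignmentSet
    truth: tuple[ChimeraCall, ...]

    @property
    def target_order(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.targets.items()]


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(_BASES, k=n))


def generate(spec: FixtureSpec) -> Fixture:
    """Generate the fixture deterministically from ``spec.seed``."""
    rng = random.Random(spec.seed)
    targets = {
        f"ref{i + 1}": _random_seq(rng, rng.randint(*spec.target_length_range))
        for i in range(spec.n_targets)
    }
    names = list(targets)
    n_chimeric = round(spec.chimera_fraction * spec.n_reads)
    chimeric_idx = set(rng.sample(range(spec.n_reads), n_chimeric))

    reads: list[SeqRecord] = []
    records: list[AlignmentRecord] = []
    truth: list[ChimeraCall] = []

    def segment(target: str, length: int) -> tuple[str, int, int, Strand]:
        tlen = len(targets[target])
        start = rng.randint(0, tlen - length)
        strand = rng.choice((Strand.FORWARD, Strand.REVERSE))
        seq = targets[target][start : start + length]
        if strand is Strand.REVERSE:
            seq = _revcomp(seq)
        return seq, start, start + length, strand

    for i in range(spec.n_reads):
        name = f"read{i + 1:05d}"
        read_len = rng.randint(*spec.read_length_range)
        if i in chimeric_idx:
            # two segments, each in [12%, 46%+] with combined >= 92%,
            # separated by an unaligned junk gap of <= 8% of the read
            gap = rng.randint(0, max(1, int(0.08 * read_len)) - 1)
            body = read_len - gap
            seg1_len = rng.randint(int(0.12 * read_len) + 1, body - int(0.12 * read_len) - 1)
            seg2_len = body - seg1_len
            t1, t2 = rng.sample(names, 2)
            s1, t1s, t1e, st1 = segment(t1, seg1_len)
            s2, t2s, t2e, st2 = segment(t2, seg2_len)
            seq = s1 + _random_seq(rng, gap) + s2
            left = AlignmentRecord(
                query_name=name, query_length=read_len,
                query_start=0, query_end=seg1_len, strand=st1,
                target_name=t1, target_length=len(targets[t1]),
                target_start=t1s, target_end=t1e,
            )
            right = AlignmentRecord(
                query_name=name, query_length=read_len,
                query_start=seg1_len + gap, query_end=read_len, strand=st2,
                target_name=t2, target_length=len(targets[t2]),
                target_start=t2s, target_end=t2e,
            )
            records.extend([left, right])
            truth.append(ChimeraCall(
                query_name=name,
                join_position=(left.query_end + right.query_start) // 2,
                left_alignment=left, right_alignment=right,
            ))
        else:
            # an ordinary read: one full-length alignment to one target
            target = rng.choice(names)
            seq, ts, te, strand = segment(target, read_len)
            records.append(AlignmentRecord(
                query_name=name, query_length=read_len,
                query_start=0, query_end=read_len, strand=strand,
                target_name=target, target_length=len(targets[target]),
                target_start=ts, target_end=te,
            ))
        noise_max = (read_len - 1) // 100  # largest span strictly under 1%
        if noise_max >= 1 and rng.random() < spec.noise_alignment_rate:
            # spurious short hit: strictly under 1% of the read length, so
            # the default length filter removes it
            noise_len = rng.randint(min(10, noise_max), noise_max)
            target = rng.choice(names)
            _, ts, te, strand = segment(target, noise_len)
            qs = rng.randint(0, read_len - noise_len)
            records.append(AlignmentRecord(
                query_name=name, query_length=read_len,
                query_start=qs, query_end=qs + noise_len, strand=strand,
                target_name=target, target_length=len(targets[target]),
                target_start=ts, target_end=te,
            ))
        reads.append(SeqRecord(name=name, sequence=seq))

    return Fixture(
        targets=targets,
        reads=tuple(reads),
        alignments=AlignmentSet(records),
        truth=tuple(sorted(truth, key=lambda c: c.query_name)),
    )


# --- serialisers (round-trip oracles for the parsers) -----------------------

SERIALIZABLE = ("paf", "sam", "blast", "psl")


def _paf_line(rec: AlignmentRecord) -> str:
    matches = min(rec.query_span, rec.target_span)
    return "\t".join(map(str, (
        rec.query_name, rec.query_length, rec.query_start, rec.query_end,
        rec.strand.value, rec.target_name, rec.target_length,
        rec.target_start, rec.target_end, matches, rec.query_span, 60,
    )))


def _sam_lines(records: Sequence[AlignmentRecord]) -> list[str]:
    lines = []
    seen: dict[str, int] = {}
    for rec in records:
        if rec.target_length > 0:
            seen.setdefault(rec.target_name, rec.target_length)
    lines.append("@HD\tVN:1.6\tSO:unknown")
    for name, length in seen.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    per_query_count: dict[str, int] = {}
    for rec in records:
        flag = 0
        if rec.strand is Strand.REVERSE:
            flag |= 0x10
        # later records of a query are written as supplementary pieces
        if per_query_count.get(rec.query_name, 0) > 0:
            flag |= 0x800
        per_query_count[rec.query_name] = per_query_count.get(rec.query_name, 0) + 1
        if rec.strand is Strand.REVERSE:
            lead = rec.query_length - rec.query_end
            trail = rec.query_start
        else:
            lead = rec.query_start
            trail = rec.query_length - rec.query_end
        aligned = min(rec.query_span, rec.target_span)
        extra = ""
        if rec.query_span > rec.target_span:
            extra = f"{rec.query_span - rec.target_span}I"
        elif rec.target_span > rec.query_span:
            extra = f"{rec.target_span - rec.query_span}D"
        cigar = (
            (f"{lead}S" if lead else "")
            + f"{aligned}M{extra}"
            + (f"{trail}S" if trail else "")
        )
        lines.append("\t".join(map(str, (
            rec.query_name, flag, rec.target_name, rec.target_start + 1, 60,
            cigar, "*", 0, 0, "*", "*",
        ))))
    return lines


def _blast_line(rec: AlignmentRecord) -> str:
    if rec.strand is Strand.REVERSE:
        sstart, send = rec.target_end, rec.target_start + 1
    else:
        sstart, send = rec.target_start + 1, rec.target_end
    return "\t".join(map(str, (
        rec.query_name, rec.target_name, "98.50", rec.query_span, 0, 0,
        rec.query_start + 1, rec.query_end, sstart, send, "1e-50", "500",
        rec.query_length, rec.target_length,
    )))


def _psl_line(rec: AlignmentRecord) -> str:
    return "\t".join(map(str, (
        rec.query_span, 0, 0, 0, 0, 0, 0, 0, rec.strand.value,
        rec.query_name, rec.query_length, rec.query_start, rec.query_end,
        rec.target_name, rec.target_length, rec.target_start, rec.target_end,
        1, f"{rec.query_span},", f"{rec.query_start},", f"{rec.target_start},",
    )))


def serialize(alignments: AlignmentSet, fmt: str, sink: IO[str]) -> None:
    """Write ``alignments`` as ``fmt`` so the matching parser round-trips.

    Supported formats: paf, sam, blast (extended with qlen/slen), psl.
    The MUMmer formats are lossy (no full query coordinates) and are
    rejected.
    """
    if fmt not in SERIALIZABLE:
        raise ValueError(
            f"cannot serialise to {fmt!r}; supported: {', '.join(SERIALIZABLE)}"
        )
    if fmt == "sam":
        for line in _sam_lines(list(alignments)):
            sink.write(line + "\n")
        return
    line_fn = {"paf": _paf_line, "blast": _blast_line, "psl": _psl_line}[fmt]
    for rec in alignments:
        sink.write(line_fn(rec) + "\n")
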
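"""Format parsers: coordinate normalisation, error handling, round-trips."""

import io
import random

import pytest

from alnviz.fixtures import serialize
from alnviz.model import AlignmentSet, Strand
from alnviz.parsers import (
    ParseError,
    parse,
    parse_blast_tab,
    parse_coords,
    parse_paf,
    parse_psl,
    parse_sam,
    parse_tiling,
)

from conftest import make_record, random_record

PAF_LINE = "q1\t1000\t0\t480\t+\tT1\t5000\t100\t590\t470\t490\t60\n"


class TestPaf:
    def test_direct_field_mapping(self):
        (rec,) = parse_paf(io.StringIO(PAF_LINE))
        assert rec == make_record()

    def test_reverse_strand_flag(self):
        (rec,) = parse_paf(io.StringIO(PAF_LINE.replace("\t+\t", "\t-\t")))
        assert rec.strand is Strand.REVERSE
        assert (rec.query_start, rec.query_end) == (0, 480)  # forward-frame

    def test_empty_file(self):
        assert len(parse_paf(io.StringIO(""))) == 0

    @pytest.mark.parametrize(
        "line",
        ["q1\t1000\t0\t480\t+\tT1\t5000\t100\t590\n", "q1\tx\t0\t480\t+\tT1\t5000\t100\t590\t1\t1\t60\n"],
    )
    def test_malformed_line_names_line_number(self, line):
        with pytest.raises(ParseError, match="line 2"):
            parse_paf(io.StringIO(PAF_LINE + line))

    def test_round_trip_random_records(self, rng):
        records = AlignmentSet(random_record(rng) for _ in range(50))
        buf = io.StringIO()
        serialize(records, "paf", buf)
        assert parse_paf(io.StringIO(buf.getvalue())) == records


def sam(*lines):
    return io.StringIO("".join(line + "\n" for line in lines))


class TestSam:
    def test_hand_walked_cigar(self):
        # 10S40M5I45M: query consumes 10+40+5+45=100, clips [10,100); target 40+45=85
        (rec,) = parse_sam(sam("q1\t0\tT1\t100\t60\t10S40M5I45M\t*\t0\t0\t*\t*"))
        assert (rec.query_length, rec.query_start, rec.query_end) == (100, 10, 100)
        assert (rec.target_start, rec.target_end) == (99, 184)
        assert rec.strand is Strand.FORWARD

    def test_reverse_strand_reflected_to_forward_frame(self):
        # stored-frame interval [10, 100) of a 100 bp read -> forward [0, 90)
        (rec,) = parse_sam(sam("q1\t16\tT1\t100\t60\t10S90M\t*\t0\t0\t*\t*"))
        assert rec.strand is Strand.REVERSE
        assert (rec.query_start, rec.query_end) == (0, 90)

    def test_hard_clips_count_toward_query_length(self):
        (rec,) = parse_sam(sam("q1\t2048\tT1\t1\t60\t30H50M20H\t*\t0\t0\t*\t*"))
        assert rec.query_length == 100
        assert (rec.query_start, rec.query_end) == (30, 80)

    def test_header_only_file_is_empty(self):
        assert len(parse_sam(sam("@HD\tVN:1.6", "@SQ\tSN:T1\tLN:5000"))) == 0

    def test_sq_header_supplies_target_length(self):
        (rec,) = parse_sam(sam("@SQ\tSN:T1\tLN:5000", "q1\t0\tT1\t1\t60\t50M\t*\t0\t0\t*\t*"))
        assert rec.target_length == 5000

    def test_missing_sq_gives_zero_target_length(self):
        (rec,) = parse_sam(sam("q1\t0\tT1\t1\t60\t50M\t*\t0\t0\t*\t*"))
        assert rec.target_length == 0

    @pytest.mark.parametrize("flag,kept", [(0, True), (4, False), (256, False), (2048, True)])
    def test_flag_filtering(self, flag, kept):
        out = parse_sam(sam(f"q1\t{flag}\tT1\t1\t60\t50M\t*\t0\t0\t*\t*"))
        assert len(out) == (1 if kept else 0)

    def test_star_cigar_skipped_with_warning(self, caplog):
        out = parse_sam(sam("q1\t0\tT1\t1\t60\t*\t*\t0\t0\t*\t*"))
        assert len(out) == 0
        assert any("no CIGAR" in r.message for r in caplog.records)

    def test_bad_flag_is_parse_error(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_sam(sam("q1\tNaN\tT1\t1\t60\t50M\t*\t0\t0\t*\t*"))

    def test_round_trip_including_reverse_strand(self, rng):
        records = AlignmentSet(random_record(rng) for _ in range(50))
        buf = io.StringIO()
        serialize(records, "sam", buf)
        assert parse_sam(io.StringIO(buf.getvalue())) == records

    def test_agrees_with_pysam_on_serialised_fixture(self, rng, tmp_path):
        pysam = pytest.importorskip("pysam")
        records = AlignmentSet(random_record(rng) for _ in range(30))
        path = tmp_path / "fixture.sam"
        with open(path, "w") as handle:
            serialize(records, "sam", handle)
        ours = list(parse_sam(open(path)))
        theirs = list(pysam.AlignmentFile(str(path), "r"))
        assert len(ours) == len(theirs)
        for mine, ref in zip(ours, theirs):
            assert mine.query_name == ref.query_name
            assert mine.target_start == ref.reference_start
            assert mine.target_end == ref.reference_end
            assert mine.query_length == ref.infer_read_length()
            assert (mine.strand is Strand.REVERSE) == ref.is_reverse


BLAST_LINE = "q1\tT1\t98.50\t480\t0\t0\t1\t480\t101\t590\t1e-50\t500"


class TestBlastTab:
    def test_one_based_inclusive_conversion(self):
        (rec,) = parse_blast_tab(io.StringIO(BLAST_LINE + "\t1000\t5000\n"))
        assert rec == make_record()

    def test_descending_subject_pair_means_reverse(self):
        line = "q1\tT1\t98.50\t480\t0\t0\t1\t480\t590\t101\t1e-50\t500\t1000\t5000\n"
        (rec,) = parse_blast_tab(io.StringIO(line))
        assert rec.strand is Strand.REVERSE
        assert (rec.target_start, rec.target_end) == (100, 590)

    def test_query_length_falls_back_to_max_observed_qend(self):
        lines = (
            "q\tT1\t99\t400\t0\t0\t1\t400\t1\t400\t0\t1\n"
            "q\tT1\t99\t300\t0\t0\t601\t900\t601\t900\t0\t1\n"
        )
        recs = list(parse_blast_tab(io.StringIO(lines)))
        assert [r.query_length for r in recs] == [900, 900]
        assert all(r.approximate for r in recs)

    def test_short_line_rejected(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_blast_tab(io.StringIO("q1\tT1\t98.5\t480\n"))

    def test_round_trip_with_qlen_slen(self, rng):
        records = AlignmentSet(random_record(rng) for _ in range(50))
        buf = io.StringIO()
        serialize(records, "blast", buf)
        assert parse_blast_tab(io.StringIO(buf.getvalue())) == records


PSL_HEADER = (
    "psLayout version 3\n"
    "\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ    \tQ   \tQ    \tQ  \tT    \tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname \tsize\tstart\tend\tname \tsize\tstart\tend\tcount\n"
    "---------------------------------------------------------------------------------------------------------------------------------------------------------------\n"
)
PSL_ROW = "480\t0\t0\t0\t0\t0\t0\t0\t+\tq1\t1000\t0\t480\tT1\t5000\t100\t590\t1\t480,\t0,\t100,\n"


class TestPsl:
    def test_direct_mapping_matches_paf_example(self):
        (rec,) = parse_psl(io.StringIO(PSL_ROW))
        assert rec == make_record()

    def test_header_block_skipped(self):
        out = parse_psl(io.StringIO(PSL_HEADER + PSL_ROW))
        assert len(out) == 1

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ParseError):
            parse_psl(io.StringIO("480\t0\t0\n"))

    def test_round_trip(self, rng):
        records = AlignmentSet(random_record(rng) for _ in range(50))
        buf = io.StringIO()
        serialize(records, "psl", buf)
        assert parse_psl(io.StringIO(buf.getvalue())) == records


def test_cross_format_equivalence(rng):
    """One synthetic set serialised as PAF, SAM, BLAST6+lens and PSL parses
    to identical normalised records."""
    records = AlignmentSet(random_record(rng) for _ in range(40))
    parsers = {
        "paf": parse_paf,
        "sam": parse_sam,
        "blast": parse_blast_tab,
        "psl": parse_psl,
    }
    parsed = {}
    for fmt, parser in parsers.items():
        buf = io.StringIO()
        serialize(records, fmt, buf)
        parsed[fmt] = parser(io.StringIO(buf.getvalue()))
    for fmt, result in parsed.items():
        assert result == records, fmt


COORDS_HEADER = (
    "/data/ref.fasta /data/qry.fasta\n"
    "NUCMER\n"
    "\n"
    "[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[LEN R]\t[LEN Q]\t[TAGS]\n"
)


def coords_row(s1, e1, s2, e2, lenr=5000, lenq=1000, ref="T1", qry="q1"):
    len1 = abs(e1 - s1) + 1
    len2 = abs(e2 - s2) + 1
    return f"{s1}\t{e1}\t{s2}\t{e2}\t{len1}\t{len2}\t97.50\t{lenr}\t{lenq}\t{ref}\t{qry}\n"


class TestCoords:
    def test_forward_row(self):
        (rec,) = parse_coords(io.StringIO(COORDS_HEADER + coords_row(101, 590, 1, 480)))
        assert rec == make_record()

    def test_reversed_query_pair_normalises_to_same_interval(self):
        fwd = parse_coords(io.StringIO(coords_row(101, 590, 101, 590)))
        rev = parse_coords(io.StringIO(coords_row(101, 590, 590, 101)))
        assert fwd[0].query_start == rev[0].query_start == 100
        assert fwd[0].query_end == rev[0].query_end == 590
        assert fwd[0].strand is Strand.FORWARD
        assert rev[0].strand is Strand.REVERSE

    def test_header_lines_contribute_no_records(self):
        assert len(parse_coords(io.StringIO(COORDS_HEADER))) == 0

    def test_ten_row_file_matches_column_slicing_oracle(self, rng):
        rows, expected = [], []
        for i in range(10):
            s1 = rng.randint(1, 4000)
            e1 = s1 + rng.randint(1, 500)
            s2 = rng.randint(1, 400)
            e2 = s2 + rng.randint(1, 500)
            rows.append(coords_row(s1, e1, s2, e2, lenq=1000 + 600, qry=f"q{i}"))
            expected.append((s1 - 1, e1, s2 - 1, e2))
        out = parse_coords(io.StringIO(COORDS_HEADER + "".join(rows)))
        assert len(out) == 10
        for rec, (ts, te, qs, qe) in zip(out, expected):
            assert (rec.target_start, rec.target_end) == (ts, te)
            assert (rec.query_start, rec.query_end) == (qs, qe)

    def test_bad_data_row_is_parse_error(self):
        with pytest.raises(ParseError, match="line 5"):
            parse_coords(io.StringIO(COORDS_HEADER + "101\t590\toops\n"))


TILING = (
    ">T1 5000 bases\n"
    "1\t500\t0\t500\t100.00\t99.00\t+\tq1\n"
    ">T2 8000 bases\n"
    "101\t600\t-10\t500\t100.00\t98.00\t-\tq2\n"
)


class TestTiling:
    def test_blocks_and_orientation(self):
        recs = list(parse_tiling(io.StringIO(TILING)))
        assert [(r.target_name, r.target_length) for r in recs] == [("T1", 5000), ("T2", 8000)]
        assert (recs[0].target_start, recs[0].target_end) == (0, 500)
        assert recs[0].strand is Strand.FORWARD
        assert recs[1].strand is Strand.REVERSE
        # query interval is the whole contig, flagged approximate
        assert (recs[0].query_start, recs[0].query_end) == (0, 500)
        assert all(r.approximate for r in recs)

    def test_data_row_before_reference_line_rejected(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_tiling(io.StringIO("1\t500\t0\t500\t100.00\t99.00\t+\tq1\n"))


class TestDispatch:
    def test_dispatch_matches_direct_parser(self, tmp_path):
        path = tmp_path / "a.paf"
        path.write_text(PAF_LINE)
        assert parse(path, "paf") == parse_paf(io.StringIO(PAF_LINE))

    def test_unknown_format_is_usage_error(self, tmp_path):
        path = tmp_path / "a.xyz"
        path.write_text("")
        with pytest.raises(ValueError, match="unknown input format"):
            parse(path, "xyz")

    def test_invariant_violation_rejected(self, tmp_path):
        path = tmp_path / "bad.paf"
        # query_end > query_length
        path.write_text("q1\t100\t0\t480\t+\tT1\t5000\t100\t590\t470\t490\t60\n")
        with pytest.raises(ParseError, match="line 1"):
            parse(path, "paf")


def test_fuzzed_lines_error_cleanly_or_yield_valid_records():
    """Parsers never emit invariant-violating records on garbage input."""
    from hypothesis import given, settings, strategies as st

    printable = st.text(
        alphabet=st.characters(min_codepoint=32, max_codepoint=126), max_size=40
    )
    token = st.one_of(printable, st.integers(-50, 5000).map(str))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.lists(token, max_size=25).map("\t".join), max_size=4))
    def check(lines):
        text = "\n".join(lines)
        for parser in (parse_paf, parse_sam, parse_blast_tab, parse_psl,
                       parse_coords, parse_tiling):
            try:
                result = parser(io.StringIO(text))
            except ParseError:
                continue
            for rec in result:
                assert 0 <= rec.query_start < rec.query_end <= rec.query_length
                assert rec.target_start < rec.target_end

    check()
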
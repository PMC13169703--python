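"""Format parsing, writing and score classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trnapanel.annotations_io import (
    FormatError,
    TRNALocus,
    classify_by_score,
    parse_trnascan_table,
    read_bed6,
    read_liftover_map,
    write_bed6,
    write_liftover_map,
    write_trnascan_table,
)


class TestTrnascanParsing:
    def test_plus_strand_row_converts_to_half_open(self):
        loci = parse_trnascan_table("chr1\t1\t101\t180\tGly\tGCC\t0\t0\t72.1\n", "g")
        (loc,) = loci
        assert (loc.chrom, loc.start, loc.end, loc.strand) == ("chr1", 100, 180, "+")
        assert loc.score == 72.1
        assert loc.introns == ()

    def test_reversed_coordinates_encode_minus_strand(self):
        (loc,) = parse_trnascan_table("chr1\t2\t180\t101\tGly\tGCC\t0\t0\t72.1\n", "g")
        assert (loc.start, loc.end, loc.strand) == (100, 180, "-")

    def test_rows_below_score_floor_are_dropped(self):
        loci = parse_trnascan_table(
            "chr1\t1\t101\t180\tGly\tGCC\t0\t0\t9.5\n", "g", score_floor=10
        )
        assert loci == []

    def test_header_lines_skipped_and_extra_columns_preserved(self):
        text = (
            "Sequence\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
            "Name    \t     \t     \t   \t    \t     \t     \t   \t     \n"
            "--------\t-----\t-----\t---\t----\t-----\t-----\t---\t-----\n"
            "chr1\t1\t101\t180\tGly\tGCC\t0\t0\t72.1\tpseudo\tnote\n"
        )
        (loc,) = parse_trnascan_table(text, "g")
        assert loc.note == "pseudo\tnote"

    def test_minus_strand_intron_in_gene_coordinates(self):
        # gene 1-based 180..101 (minus); intron reported in transcription
        # order 160..150 -> gene-relative [20, 31)
        (loc,) = parse_trnascan_table(
            "chr1\t1\t180\t101\tLeu\tCAA\t160\t150\t60\n", "g"
        )
        assert loc.introns == ((20, 31),)

    @pytest.mark.parametrize(
        "row",
        [
            "chr1\t1\t101\t180\tGly\tGCC\t0\t0",  # too few columns
            "chr1\t1\tX\t180\tGly\tGCC\t0\t0\t72.1",  # non-numeric coordinate
        ],
    )
    def test_malformed_rows_raise_with_line_number(self, row):
        with pytest.raises(FormatError, match="line 1"):
            parse_trnascan_table(row + "\n", "g")

    def test_duplicate_locus_id_rejected(self):
        text = (
            "chr1\t1\t101\t180\tGly\tGCC\t0\t0\t72.1\n"
            "chr1\t1\t301\t380\tGly\tGCC\t0\t0\t72.1\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            parse_trnascan_table(text, "g")

    def test_round_trip_reproduces_loci_exactly(self):
        rng = np.random.default_rng(7)
        loci = []
        for i in range(30):
            start = int(rng.integers(0, 10_000))
            length = int(rng.integers(60, 120))
            strand = "+" if rng.random() < 0.5 else "-"
            introns = ()
            if rng.random() < 0.3:
                s = int(rng.integers(10, 40))
                introns = ((s, s + int(rng.integers(5, 15))),)
            loci.append(
                TRNALocus(
                    locus_id=f"chr1.trna{i + 1}",
                    genome="g",
                    chrom="chr1",
                    start=start,
                    end=start + length,
                    strand=strand,
                    isotype="Gly",
                    anticodon="GCC",
                    score=round(float(rng.uniform(10, 90)), 1),
                    introns=introns,
                )
            )
        assert parse_trnascan_table(write_trnascan_table(loci), "g") == loci


class TestScoreClassification:
    def test_threshold_is_strict(self):
        loci = [
            TRNALocus(f"c.trna{i}", "g", "c", 0, 70, "+", "Gly", "GCC", s)
            for i, s in enumerate([50.0, 50.1, 10.0])
        ]
        part = classify_by_score(loci, 50)
        assert [l.score for l in part.high] == [50.1]
        assert sorted(l.score for l in part.low) == [10.0, 50.0]

    def test_empty_input_gives_empty_partition(self):
        part = classify_by_score([], 50)
        assert part.high == [] and part.low == []

    @given(
        scores=st.lists(st.floats(min_value=0, max_value=120), max_size=40),
        threshold=st.floats(min_value=0, max_value=100),
    )
    def test_partition_is_exhaustive_and_disjoint(self, scores, threshold):
        loci = [
            TRNALocus(f"c.trna{i}", "g", "c", 0, 70, "+", "Gly", "GCC", s)
            for i, s in enumerate(scores)
        ]
        part = classify_by_score(loci, threshold)
        assert sorted(l.locus_id for l in part.high + part.low) == sorted(
            l.locus_id for l in loci
        )
        assert not {l.locus_id for l in part.high} & {l.locus_id for l in part.low}


class TestLiftoverMap:
    def test_reads_records_in_file_order_and_skips_comments(self):
        text = (
            "# comment\n"
            "g1\tc1\t0\t100\tg2\tc1\t50\t150\t+\n"
            "g1\tc1\t200\t300\tg2\tc2\t0\t100\t-\n"
        )
        recs = read_liftover_map(text)
        assert len(recs) == 2
        assert recs[0].dst_start == 50 and recs[1].dst_strand == "-"

    def test_empty_source_interval_is_an_error(self):
        with pytest.raises(FormatError, match="line 1"):
            read_liftover_map("g1\tc1\t5\t5\tg2\tc1\t5\t6\t+\n")

    def test_round_trip(self):
        text = "g1\tc1\t0\t100\tg2\tc1\t50\t150\t+\n"
        recs = read_liftover_map(text)
        assert write_liftover_map(recs) == text


class TestBed6:
    def test_score_scaled_and_clamped(self):
        loci = [
            TRNALocus("c.trna1", "g", "c", 10, 80, "-", "Gly", "GCC", 72.14),
            TRNALocus("c.trna2", "g", "c", 90, 160, "+", "Ser", "AGA", 150.0),
        ]
        recs = read_bed6(write_bed6(loci))
        assert recs[0] == ("c", 10, 80, "c.trna1", 721, "-")
        assert recs[1].score == 1000  # clamped
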
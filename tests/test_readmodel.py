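import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribostop.readmodel import (
    AnnotationError,
    ReadRecord,
    annotate_relative,
    by_gene,
    classify_size,
    collapse_umis,
    load_alignments,
    parse_annotation,
    read_table,
    records_to_frame,
    frame_to_records,
    to_stop_relative,
    write_table,
)
from .conftest import make_tm, reads_frame


@pytest.mark.parametrize(
    "length,expected",
    [(14, "other"), (15, "short"), (18, "short"), (19, "mid"), (21, "mid"),
     (26, "mid"), (27, "other"), (28, "long"), (30, "long"), (31, "other")],
)
def test_size_classes_cover_gel_cut_bounds(length, expected):
    assert classify_size(length) == expected


class TestAnnotationParsing:
    def test_plus_strand_stop_in_transcript_space(self, toy_gff_text):
        tms = {t.transcript_id: t for t in parse_annotation(toy_gff_text, from_string=True)}
        a = tms["tA"]
        # CDS 100..199 (0-based) on an exon starting at 100: stop codon
        # occupies genomic 197-199, transcript offset 97
        assert a.stop_codon_pos == 97
        assert a.spliced_length == 200
        assert a.cds_length == 100
        assert a.cds_start_pos == 0

    def test_minus_strand_is_flipped_to_same_coordinates(self, toy_gff_text):
        tms = {t.transcript_id: t for t in parse_annotation(toy_gff_text, from_string=True)}
        assert tms["tB"].stop_codon_pos == tms["tA"].stop_codon_pos
        assert tms["tB"].spliced_length == tms["tA"].spliced_length

    def test_multi_isoform_gene_counts_distinct_stops(self, toy_gff_text):
        tms = parse_annotation(toy_gff_text, from_string=True)
        stops = {t.n_annotated_stops for t in tms if t.gene_id == "geneC"}
        assert stops == {2}
        assert all(t.n_annotated_stops == 1 for t in tms if t.gene_id == "geneA")

    def test_orphan_cds_skipped_with_warning(self, toy_gff_text, caplog):
        with caplog.at_level("WARNING"):
            tms = parse_annotation(toy_gff_text, from_string=True)
        assert not any(t.gene_id == "missing_t" for t in tms)
        assert any("no parent" in r.message for r in caplog.records)

    def test_malformed_line_names_line_number(self):
        bad = "chr1\ttoy\tgene\t1\t100\t.\t+\t.\n"  # 8 fields
        with pytest.raises(AnnotationError, match="line 1"):
            parse_annotation(bad, from_string=True)

    def test_by_gene_keeps_longest_cds(self, toy_gff_text):
        idx = by_gene(parse_annotation(toy_gff_text, from_string=True))
        assert idx["geneC"].transcript_id == "tC2"


class TestUmiCollapse:
    def test_exact_duplicates_collapse(self):
        df = reads_frame([("g", 10, 27, "unknown", "ACGTAA"), ("g", 10, 27, "unknown", "ACGTAA")])
        assert len(collapse_umis(df)) == 1

    def test_distinct_umis_survive(self):
        df = reads_frame([("g", 10, 27, "unknown", "ACGTAA"), ("g", 10, 27, "unknown", "ACGTAT")])
        assert len(collapse_umis(df)) == 2

    def test_counts_distinct_keys(self):
        rows = []
        for _ in range(4):
            rows.append(("g", 10, 27, "unknown", "AAAAAA"))
        for _ in range(3):
            rows.append(("g", 10, 24, "unknown", "AAAAAA"))  # different length
        for _ in range(3):
            rows.append(("g", 12, 29, "unknown", "CCCCCC"))
        assert len(collapse_umis(reads_frame(rows))) == 3

    def test_empty_umis_retained_each(self, caplog):
        df = reads_frame([("g", 10, 27, "unknown", ""), ("g", 10, 27, "unknown", "")])
        with caplog.at_level("WARNING"):
            out = collapse_umis(df)
        assert len(out) == 2

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["g1", "g2"]),
                st.integers(0, 50),
                st.integers(15, 30),
                st.sampled_from(["AAA", "CCC", ""]),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_collapse_idempotent(self, raw):
        df = reads_frame([(g, e5, e5 + L - 1, "unknown", u) for g, e5, L, u in raw])
        once = collapse_umis(df)
        twice = collapse_umis(once)
        pd.testing.assert_frame_equal(once, twice)


class TestStopRelative:
    tm = make_tm("g", cds_len=100)  # stop at 97

    def test_end3_on_stop_is_zero(self):
        r = ReadRecord("g", 80, 97)
        assert to_stop_relative(r, self.tm, "3p") == 0

    def test_last_stop_nt_is_plus_two(self):
        r = ReadRecord("g", 82, 99)
        assert to_stop_relative(r, self.tm, "3p") == 2

    def test_18mer_anchored_5p(self):
        r = ReadRecord("g", 97 - 17, 97)
        assert to_stop_relative(r, self.tm, "5p") == -17

    @given(st.integers(0, 80), st.integers(15, 30))
    @settings(max_examples=50, deadline=None)
    def test_anchor_difference_is_length_minus_one(self, e5, L):
        r = ReadRecord("g", e5, e5 + L - 1)
        assert (
            to_stop_relative(r, self.tm, "3p") - to_stop_relative(r, self.tm, "5p")
            == r.length - 1
        )

    def test_gene_mismatch_raises(self):
        with pytest.raises(ValueError):
            to_stop_relative(ReadRecord("other", 0, 20), self.tm)


def test_table_round_trip(tmp_path):
    recs = [
        ReadRecord("g1", 5, 22, "OH", "ACGTAC"),
        ReadRecord("g1", 7, 34, "P", "TTTTTT"),
        ReadRecord("g2", 0, 17, "unknown", ""),
    ]
    path = tmp_path / "reads.tsv.gz"
    write_table(records_to_frame(recs), path, meta={"seed": 1})
    back = frame_to_records(read_table(path))
    assert back == recs


def test_annotate_relative_drops_unknown_genes(caplog):
    tms = {"g": make_tm("g", cds_len=100)}
    df = reads_frame([("g", 90, 104), ("ghost", 0, 20)])
    with caplog.at_level("WARNING"):
        out = annotate_relative(df, tms)
    assert len(out) == 1
    assert out["rel3"].iloc[0] == 104 - 97


SAM_TEXT = """@HD\tVN:1.6\tSO:unknown
@SQ\tSN:chr1\tLN:400
@SQ\tSN:chr2\tLN:400
r1_ACGTACGT\t0\tchr1\t151\t30\t20M\t*\t0\t0\t{seq20}\t*
rlow_CCCCCCCC\t0\tchr1\t151\t2\t20M\t*\t0\t0\t{seq20}\t*
rrev_GGGGGGGG\t16\tchr2\t151\t30\t20M\t*\t0\t0\t{seq20}\t*
ranti_TTTTTTTT\t0\tchr2\t151\t30\t20M\t*\t0\t0\t{seq20}\t*
rout_AAAAAAAA\t0\tchr1\t395\t30\t20M\t*\t0\t0\t{seq20}\t*
""".format(seq20="A" * 20)


def test_sam_projection_and_filters(tmp_path, toy_gff_text):
    tms = parse_annotation(toy_gff_text, from_string=True)
    sam = tmp_path / "toy.sam"
    sam.write_text(SAM_TEXT)
    df = load_alignments(sam, tms, mapq_min=10)
    # r1: genomic 150..169 on exon starting at 100 -> transcript 50..69
    fwd = df[df["umi"] == "ACGTACGT"].iloc[0]
    assert (fwd["gene_id"], fwd["end5"], fwd["end3"]) == ("geneA", 50, 69)
    # minus-strand gene: genomic 150..169 on exon 100..299 -> transcript 130..149
    rev = df[df["umi"] == "GGGGGGGG"].iloc[0]
    assert (rev["gene_id"], rev["end5"], rev["end3"]) == ("geneB", 130, 149)
    # low MAPQ, antisense and off-exon reads are dropped
    assert set(df["umi"]) == {"ACGTACGT", "GGGGGGGG"}
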
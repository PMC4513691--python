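"""Format I/O: BED dialects, GFF3 conversion, BedGraph coverage vs per-base oracle."""

import numpy as np
import pytest

from ngstk.formats import (
    BedParseError,
    bed_to_bedgraph,
    gff3_to_bed12,
    read_bed,
    read_chrom_sizes,
    read_gff3,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_gff3,
    Gff3Record,
)
from ngstk.intervals import Bed12Record, ScoredFeature

from conftest import pileup_oracle


class TestReadBed:
    def test_bed6_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t+\n")
        (feat,) = read_bed(p)
        assert feat == ScoredFeature("chr1", 100, 200, "+", name="g1", score=0)

    def test_bed4_defaults(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tg1\n")
        (feat,) = read_bed(p)
        assert feat.strand == "." and feat.score == 0

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_header_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nbrowser position chr1\nchr1\t0\t5\tg\t0\t+\n")
        assert len(read_bed(p)) == 1

    def test_zero_length_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t+\nchr1\t300\t300\tg2\t0\t+\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_mixed_columns_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t+\nchr1\t300\t400\tg2\n")
        with pytest.raises(BedParseError, match="mixed column"):
            read_bed(p)

    def test_bed12_roundtrip_exact_line(self, tmp_path):
        rec = Bed12Record(
            chrom="chr1", chromStart=100, chromEnd=400, name="t2", score=0, strand="+",
            thickStart=100, thickEnd=400, itemRgb="0", blockCount=2,
            blockSizes=(100, 100), blockStarts=(0, 200),
        )
        p = tmp_path / "a.bed"
        write_bed([rec], p)
        line = p.read_text().strip()
        assert line.split("\t")[10] == "100,100"
        assert line.split("\t")[11] == "0,200"
        assert read_bed(p) == [rec]

    def test_write_read_roundtrip_fixture(self, tmp_path, fixture_set):
        recs = fixture_set["bed12"]
        p = tmp_path / "x.bed"
        write_bed(recs, p)
        assert read_bed(p) == recs


class TestGff3:
    def _rec(self, start, end, t="gene", attrs=None):
        return Gff3Record("chr1", "src", t, start, end, ".", "+", ".",
                          attrs if attrs is not None else {"locus_tag": "b0001"})

    def test_coordinate_shift(self):
        (rec,) = gff3_to_bed12([self._rec(1, 100)])
        assert (rec.chromStart, rec.chromEnd, rec.blockCount) == (0, 100, 1)

    def test_one_bp_feature(self):
        (rec,) = gff3_to_bed12([self._rec(500, 500)])
        assert (rec.chromStart, rec.chromEnd) == (499, 500)

    def test_type_filter(self):
        assert gff3_to_bed12([self._rec(1, 100, t="region")]) == []

    def test_name_precedence(self):
        attrs = {"ID": "id1", "Name": "n1", "locus_tag": "lt1"}
        assert gff3_to_bed12([self._rec(1, 10, attrs=attrs)])[0].name == "lt1"
        del attrs["locus_tag"]
        assert gff3_to_bed12([self._rec(1, 10, attrs=dict(attrs))])[0].name == "n1"
        assert gff3_to_bed12([self._rec(1, 10, attrs={"ID": "id1"})])[0].name == "id1"

    def test_missing_identifiers_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipping"):
            out = gff3_to_bed12([self._rec(1, 10, attrs={})])
        assert out == []

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(BedParseError):
            Gff3Record("chr1", "s", "gene", 0, 10, ".", "+", ".", {})

    def test_file_roundtrip(self, tmp_path, fixture_set):
        recs = read_gff3(fixture_set["paths"]["gff3"])
        p = tmp_path / "x.gff3"
        write_gff3(recs, p)
        assert read_gff3(p) == recs

    def test_gtf_attribute_dialect(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\tgene\t1\t50\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n')
        (rec,) = read_gff3(p)
        assert rec.attributes == {"gene_id": "g1", "transcript_id": "t1"}


def _feat(start, end, strand="+", chrom="chr1"):
    return ScoredFeature(chrom, start, end, strand, name=f"f{start}")


class TestBedToBedGraph:
    def test_single_interval(self):
        track = bed_to_bedgraph([_feat(100, 200)])
        assert track.lines == [("chr1", 100, 200, 1)]

    def test_overlap_steps(self):
        track = bed_to_bedgraph([_feat(100, 300), _feat(200, 400)])
        assert track.lines == [
            ("chr1", 100, 200, 1),
            ("chr1", 200, 300, 2),
            ("chr1", 300, 400, 1),
        ]

    def test_strand_specific_partition(self):
        plus, minus = bed_to_bedgraph(
            [_feat(0, 10, "+"), _feat(5, 15, "-")], strand_specific=True
        )
        assert plus.lines == [("chr1", 0, 10, 1)]
        assert minus.lines == [("chr1", 5, 15, 1)]

    def test_only_plus_input_gives_empty_minus(self):
        plus, minus = bed_to_bedgraph([_feat(0, 10, "+")], strand_specific=True)
        assert minus.lines == []

    def test_unstranded_goes_to_plus_with_warning(self):
        with pytest.warns(UserWarning, match=r"\(\+\) track"):
            plus, minus = bed_to_bedgraph([_feat(0, 10, ".")], strand_specific=True)
        assert len(plus.lines) == 1

    def test_matches_per_base_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(1, 30))
            feats = []
            for _ in range(n):
                start = int(rng.integers(0, 900))
                feats.append(_feat(start, start + int(rng.integers(1, 100)),
                                   chrom=f"chr{rng.integers(1, 3)}"))
            track = bed_to_bedgraph(feats)
            assert track.lines == pileup_oracle((f.chrom, f.start, f.end) for f in feats)

    def test_coverage_conservation(self):
        rng = np.random.default_rng(11)
        feats = [_feat(int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 5000, 50), rng.integers(1, 200, 50))]
        track = bed_to_bedgraph(feats)
        assert track.total_signal() == sum(len(f) for f in feats)

    def test_write_format(self, tmp_path):
        p = tmp_path / "x.bedGraph"
        write_bedgraph(bed_to_bedgraph([_feat(100, 200)]), p)
        assert p.read_text() == "chr1\t100\t200\t1\n"


def test_chrom_sizes_roundtrip(tmp_path):
    sizes = {"chr1": 10000, "chr2": 5000}
    p = tmp_path / "g.chrom.sizes"
    write_chrom_sizes(sizes, p)
    assert read_chrom_sizes(p) == sizes
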
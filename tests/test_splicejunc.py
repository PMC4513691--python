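"""Splice junctions: dialect parsing, BED12 encoding, classification, motifs."""

import pytest

from ngstk.fixtures import make_junction_bed6
from ngstk.splicejunc import (
    SpliceJunction,
    classify_junctions,
    introns_from_bed12,
    junction_to_bed12,
    parse_junction_bed6,
    splice_site_motifs,
)
from ngstk.intervals import GenomicInterval


def _write_junc(path, lines):
    path.write_text("".join(l + "\n" for l in lines))
    return path


class TestParse:
    def test_segemehl_dialect(self, tmp_path):
        p = _write_junc(tmp_path / "j.bed", ["chr1\t200\t500\tsplits:7:7:7:N:P\t0\t+"])
        (j,) = parse_junction_bed6(p)
        assert (j.donor_end, j.acceptor_start, j.strand, j.support) == (200, 500, "+", 7)

    def test_min_support_threshold(self, tmp_path):
        p = _write_junc(tmp_path / "j.bed", ["chr1\t200\t500\tsplits:7:7:7:N:P\t0\t+"])
        assert parse_junction_bed6(p, min_support=10) == []
        assert len(parse_junction_bed6(p, min_support=7)) == 1

    def test_dedup_sums_support(self, tmp_path):
        p = _write_junc(tmp_path / "j.bed", [
            "chr1\t200\t500\tsplits:3:3:3:N:P\t0\t+",
            "chr1\t200\t500\tsplits:4:4:4:N:P\t0\t+",
        ])
        (j,) = parse_junction_bed6(p)
        assert j.support == 7

    def test_dedup_conserves_total_support(self, tmp_path, fixture_set):
        juncs = parse_junction_bed6(fixture_set["paths"]["junction_bed"])
        assert sum(j.support for j in juncs) == sum(
            fixture_set["truth"].junctions.values())

    def test_unparsable_name_falls_back_to_score(self, tmp_path):
        p = _write_junc(tmp_path / "j.bed", ["chr1\t200\t500\tweird_name\t9\t+"])
        with pytest.warns(UserWarning, match="falling back"):
            (j,) = parse_junction_bed6(p)
        assert j.support == 9

    def test_generic_dialect_uses_score(self, tmp_path):
        p = _write_junc(tmp_path / "j.bed", ["chr1\t200\t500\tanything\t4\t+"])
        (j,) = parse_junction_bed6(p, dialect="generic")
        assert j.support == 4

    def test_zero_support_dropped(self, tmp_path):
        p = _write_junc(tmp_path / "j.bed", ["chr1\t200\t500\tx\t0\t+"])
        with pytest.warns(UserWarning):
            assert parse_junction_bed6(p, dialect="generic") == []


class TestToBed12:
    def test_block_arithmetic(self):
        j = SpliceJunction("chr1", 200, 500, "+", support=7)
        rec = junction_to_bed12(j, anchor=10)
        assert (rec.chromStart, rec.chromEnd) == (190, 510)
        assert rec.blockSizes == (10, 10)
        assert rec.blockStarts == (0, 310)

    def test_left_clamp_shrinks_first_block(self):
        j = SpliceJunction("chr1", 5, 100, "+")
        rec = junction_to_bed12(j, anchor=10)
        assert rec.chromStart == 0
        assert rec.blockSizes == (5, 10)

    def test_roundtrips_intron_boundaries(self, fixture_set):
        juncs = parse_junction_bed6(fixture_set["paths"]["junction_bed"])
        for j in juncs:
            rec = junction_to_bed12(j, anchor=8)
            blocks = rec.block_intervals()
            assert blocks[0][1] == j.donor_end
            assert blocks[1][0] == j.acceptor_start

    def test_bad_anchor(self):
        with pytest.raises(ValueError):
            junction_to_bed12(SpliceJunction("chr1", 200, 500, "+"), anchor=0)


class TestClassify:
    def test_exact_match_known(self):
        j = SpliceJunction("chr1", 200, 500, "+")
        intron = GenomicInterval("chr1", 200, 500, "+")
        known, novel = classify_junctions([j], [intron])
        assert known == [j] and novel == []

    def test_one_nt_shift_is_novel(self):
        j = SpliceJunction("chr1", 201, 501, "+")
        intron = GenomicInterval("chr1", 200, 500, "+")
        known, novel = classify_junctions([j], [intron])
        assert known == [] and novel == [j]

    def test_tolerance_relaxes(self):
        j = SpliceJunction("chr1", 201, 501, "+")
        intron = GenomicInterval("chr1", 200, 500, "+")
        known, _ = classify_junctions([j], [intron], tolerance=1)
        assert known == [j]

    def test_empty_annotation_all_novel(self):
        j = SpliceJunction("chr1", 200, 500, "+")
        known, novel = classify_junctions([j], [])
        assert novel == [j]

    def test_fixture_closure(self, tmp_path, fixture_set):
        """Simulated junctions classify 100% known; jittered ones 100% novel."""
        introns = introns_from_bed12(fixture_set["bed12"])
        juncs = parse_junction_bed6(fixture_set["paths"]["junction_bed"])
        assert juncs, "fixture produced no junction reads"
        known, novel = classify_junctions(juncs, introns)
        assert len(known) == len(juncs) and not novel

        jittered_path = tmp_path / "jitter.bed"
        make_junction_bed6(fixture_set["truth"].junctions, jittered_path, jitter=1)
        jit = parse_junction_bed6(jittered_path)
        known, novel = classify_junctions(jit, introns)
        assert len(novel) == len(jit) and not known


class TestMotifs:
    def _fasta(self, tmp_path, seq, name="chr1"):
        p = tmp_path / "g.fa"
        p.write_text(f">{name}\n{seq}\n")
        return p

    def test_plus_strand_canonical(self, tmp_path):
        seq = "A" * 200 + "GT" + "C" * 296 + "AG" + "A" * 200
        fa = self._fasta(tmp_path, seq)
        (m,) = splice_site_motifs([SpliceJunction("chr1", 200, 500, "+")], fa)
        assert (m["donor"], m["acceptor"], m["canonical"]) == ("GT", "AG", True)

    def test_minus_strand_canonical_from_ct_ac(self, tmp_path):
        seq = "A" * 200 + "CT" + "C" * 296 + "AC" + "A" * 200
        fa = self._fasta(tmp_path, seq)
        (m,) = splice_site_motifs([SpliceJunction("chr1", 200, 500, "-")], fa)
        assert (m["donor"], m["acceptor"], m["canonical"]) == ("GT", "AG", True)

    def test_all_a_genome_non_canonical(self, tmp_path):
        fa = self._fasta(tmp_path, "A" * 700)
        (m,) = splice_site_motifs([SpliceJunction("chr1", 200, 500, "+")], fa)
        assert (m["donor"], m["acceptor"], m["canonical"]) == ("AA", "AA", False)

    def test_out_of_bounds_flagged_nn(self, tmp_path):
        fa = self._fasta(tmp_path, "A" * 100)
        (m,) = splice_site_motifs([SpliceJunction("chr1", 99, 500, "+")], fa)
        assert m["donor"] == "NN" and not m["in_bounds"]

    def test_unknown_chrom_raises(self, tmp_path):
        fa = self._fasta(tmp_path, "A" * 100)
        with pytest.raises(KeyError):
            splice_site_motifs([SpliceJunction("chrX", 10, 50, "+")], fa)

    def test_fixture_positive_controls(self, fixture_set):
        """Generator-forced GT..AG introns are all flagged canonical."""
        juncs = parse_junction_bed6(fixture_set["paths"]["junction_bed"])
        motifs = splice_site_motifs(juncs, fixture_set["paths"]["fasta"])
        assert motifs and all(m["canonical"] for m in motifs)
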
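"""Interval data model: extension arithmetic, chain/BED12 conversion, invariants."""

import pytest
from hypothesis import given, settings, strategies as st

from ngstk.intervals import (
    Bed12Record,
    FeatureChain,
    FeatureLine,
    GenomicInterval,
    InvariantError,
    ScoredFeature,
    bed12_to_chain,
    chain_to_bed12,
    extend_interval,
    sort_and_validate_chain,
)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "start,end,strand",
        [(-1, 10, "+"), (10, 10, "+"), (20, 10, "+"), (0, 10, "x")],
    )
    def test_invalid_rejected(self, start, end, strand):
        with pytest.raises(InvariantError):
            GenomicInterval("chr1", start, end, strand)

    def test_length_and_overlap(self):
        a = GenomicInterval("chr1", 100, 200, "+")
        assert len(a) == 100
        assert a.overlaps(GenomicInterval("chr1", 199, 300))
        assert not a.overlaps(GenomicInterval("chr1", 200, 300))  # half-open abutment
        assert not a.overlaps(GenomicInterval("chr2", 100, 200))

    def test_scored_feature_validation(self):
        with pytest.raises(InvariantError):
            ScoredFeature("chr1", 0, 10, "+", name="a\tb")
        with pytest.raises(InvariantError):
            ScoredFeature("chr1", 0, 10, "+", name="   ")
        with pytest.warns(UserWarning, match="outside"):
            ScoredFeature("chr1", 0, 10, "+", name="x", score=5000)


class TestExtendInterval:
    @pytest.mark.parametrize(
        "strand,side,amount,clen,expect",
        [
            ("+", "five_prime", 50, 1000, (50, 200)),
            ("-", "five_prime", 50, 300, (100, 250)),
            ("+", "three_prime", 50, 300, (100, 250)),
            ("-", "three_prime", 50, 1000, (50, 200)),
            (".", "five_prime", 50, 1000, (50, 200)),  # "." behaves as "+"
            ("+", "both", 50, 1000, (50, 250)),
        ],
    )
    def test_strand_aware_sides(self, strand, side, amount, clen, expect):
        iv = GenomicInterval("chr1", 100, 200, strand)
        out = extend_interval(iv, side, amount, clen)
        assert (out.start, out.end) == expect

    def test_zero_amount_is_identity(self):
        iv = GenomicInterval("chr1", 100, 200, "+")
        assert extend_interval(iv, "both", 0, 500) == iv

    def test_clamping(self):
        iv = GenomicInterval("chr1", 10, 20, "+")
        out = extend_interval(iv, "both", 50, 100)
        assert (out.start, out.end) == (0, 70)

    def test_errors(self):
        iv = GenomicInterval("chr1", 100, 200, "+")
        with pytest.raises(ValueError):
            extend_interval(iv, "both", -1, 500)
        with pytest.raises(ValueError):
            extend_interval(iv, "both", 10, 150)  # chrom shorter than interval

    @given(
        start=st.integers(0, 500),
        length=st.integers(1, 200),
        amount=st.integers(0, 300),
        strand=st.sampled_from(["+", "-", "."]),
        side=st.sampled_from(["five_prime", "three_prime", "both"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_containment(self, start, length, amount, strand, side):
        """Output always contains the input; growth is exactly `amount` per side unless clamped."""
        iv = GenomicInterval("chr1", start, start + length, strand)
        clen = 1000
        out = extend_interval(iv, side, amount, clen)
        assert out.start <= iv.start and out.end >= iv.end
        sides = 2 if side == "both" else 1
        grown = (iv.start - out.start) + (out.end - iv.end)
        clamped = out.start == 0 or out.end == clen
        if not clamped:
            assert grown == sides * amount
        else:
            assert grown <= sides * amount


def _chain(coords, chrom="chr1", strand="+"):
    return sort_and_validate_chain(
        [ScoredFeature(chrom, s, e, strand, name=f"f{i}") for i, (s, e) in enumerate(coords)]
    )


class TestChains:
    def test_sorting(self):
        c = _chain([(300, 400), (100, 200)])
        assert [(f.start, f.end) for f in c.features] == [(100, 200), (300, 400)]

    def test_overlap_rejected(self):
        with pytest.raises(InvariantError, match="overlap"):
            _chain([(100, 250), (200, 300)])

    def test_mixed_chrom_rejected(self):
        feats = [
            ScoredFeature("chr1", 0, 10, "+", name="a"),
            ScoredFeature("chr2", 20, 30, "+", name="b"),
        ]
        with pytest.raises(InvariantError, match="chrom"):
            sort_and_validate_chain(feats)

    def test_empty_rejected(self):
        with pytest.raises(InvariantError):
            sort_and_validate_chain([])

    def test_feature_line_label_consistency(self):
        line = FeatureLine()
        line.add(_chain([(0, 10)]))
        assert "exon" in line
        with pytest.raises(InvariantError):
            FeatureLine(chains={"intron": [_chain([(0, 10)])]})  # chain_type is "exon"


class TestBed12Conversion:
    def test_single_block(self):
        rec = chain_to_bed12(_chain([(100, 400)]), name="t1")
        assert (rec.chromStart, rec.chromEnd) == (100, 400)
        assert rec.blockCount == 1
        assert rec.blockSizes == (300,)
        assert rec.blockStarts == (0,)

    def test_two_exons(self):
        rec = chain_to_bed12(_chain([(100, 200), (300, 400)]), name="t2")
        assert rec.blockCount == 2
        assert rec.blockSizes == (100, 100)
        assert rec.blockStarts == (0, 200)
        assert rec.chromEnd == 400
        assert (rec.thickStart, rec.thickEnd) == (100, 400)

    def test_inverse(self):
        rec = chain_to_bed12(_chain([(100, 200), (300, 400)]), name="t2")
        chain = bed12_to_chain(rec)
        assert [(f.start, f.end) for f in chain.features] == [(100, 200), (300, 400)]

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 300)),
            min_size=1,
            max_size=8,
        ),
        st.sampled_from(["+", "-"]),
    )
    @settings(max_examples=150, deadline=None)
    def test_roundtrip_property(self, raw, strand):
        """chain -> BED12 -> chain preserves coordinates, order and strand."""
        # lay out non-overlapping blocks left to right
        feats, pos = [], 0
        for offset, length in raw:
            pos += offset + 1
            feats.append(
                ScoredFeature("chr1", pos, pos + length, strand, name=f"f{pos}")
            )
            pos += length
        chain = sort_and_validate_chain(feats)
        rec = chain_to_bed12(chain, name="t")
        back = bed12_to_chain(rec)
        assert [(f.start, f.end) for f in back.features] == [
            (f.start, f.end) for f in chain.features
        ]
        assert back.strand == chain.strand

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(blockCount=2, blockSizes=(10,), blockStarts=(0, 20)),
            dict(blockStarts=(5, 20)),  # first blockStart not 0
            dict(blockSizes=(30, 10), blockStarts=(0, 20)),  # blocks overlap
            dict(chromEnd=999),  # block arithmetic broken
            dict(thickStart=50),  # thick outside span
        ],
    )
    def test_invariant_violations(self, kwargs):
        base = dict(
            chrom="chr1", chromStart=100, chromEnd=230, name="x", score=0, strand="+",
            thickStart=100, thickEnd=230, itemRgb="0", blockCount=2,
            blockSizes=(10, 10), blockStarts=(0, 120),
        )
        base.update(kwargs)
        with pytest.raises(InvariantError):
            Bed12Record(**base)
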
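"""Splice-junction identification and characterization.

A splice junction is the (donor_end, acceptor_start) boundary pair of an
intron inferred from gapped read alignments: ``donor_end`` is the 0-based
coordinate one past the last exonic base on the left, ``acceptor_start``
the first exonic base on the right, so ``[donor_end, acceptor_start)`` is
the intron. Canonical junctions show GT at the intron 5' end and AG at
the 3' end after strand correction.

Split-read mappers report junctions as BED6 whose interval spans the
intron; the name-field grammar differs per mapper, so parsing is
dialect-pluggable. The built-in ``segemehl`` dialect reads the read
support from the colon-separated name (``splits:<reads>:...``); the
``generic`` fallback takes the score column as support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

from pyfaidx import Fasta

from .formats import read_bed
from .intervals import Bed12Record, GenomicInterval

__all__ = [
    "SpliceJunction",
    "parse_junction_bed6",
    "junction_to_bed12",
    "classify_junctions",
    "introns_from_bed12",
    "splice_site_motifs",
    "junction_summary_rows",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceJunction:
    chrom: str
    donor_end: int  # 0-based: first intronic base on the left
    acceptor_start: int  # 0-based: first exonic base on the right
    strand: str
    support: int = 1
    source_name: str = ""

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError(
                f"intron must be >= 1 nt: donor_end {self.donor_end} "
                f">= acceptor_start {self.acceptor_start}"
            )
        if self.support < 1:
            raise ValueError(f"support must be >= 1, got {self.support}")

    @property
    def key(self):
        return (self.chrom, self.donor_end, self.acceptor_start, self.strand)


def _segemehl_support(name: str):
    """segemehl name grammar: colon-separated, 'splits:<reads>:...'."""
    tokens = name.split(":")
    if len(tokens) >= 2 and tokens[0] == "splits":
        try:
            return int(tokens[1])
        except ValueError:
            return None
    return None


_DIALECTS = {"segemehl": _segemehl_support, "generic": lambda name: None}


def parse_junction_bed6(path, min_support: int = 1, dialect: str = "segemehl") -> list:
    """Parse mapper junction BED6 into deduplicated SpliceJunctions.

    The BED interval spans the intron. Junctions identical in
    (chrom, donor_end, acceptor_start, strand) are merged with summed
    support; junctions below ``min_support`` are then dropped.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    name_parser = _DIALECTS[dialect]
    merged: dict = {}
    order: list = []
    for feat in read_bed(path):
        support = name_parser(feat.name)
        if support is None:
            if dialect != "generic":
                warnings.warn(
                    f"name {feat.name!r} unparsable under dialect {dialect!r}; "
                    "falling back to score column"
                )
            support = int(feat.score)
        if support < 1:
            warnings.warn(
                f"junction {feat.chrom}:{feat.start}-{feat.end} has support "
                f"{support}; dropped"
            )
            continue
        key = (feat.chrom, feat.start, feat.end, feat.strand)
        if key in merged:
            merged[key] = replace(merged[key], support=merged[key].support + support)
        else:
            merged[key] = SpliceJunction(
                chrom=feat.chrom,
                donor_end=feat.start,
                acceptor_start=feat.end,
                strand=feat.strand,
                support=support,
                source_name=feat.name,
            )
            order.append(key)
    return [merged[k] for k in order if merged[k].support >= min_support]


def junction_to_bed12(j: SpliceJunction, anchor: int = 10) -> Bed12Record:
    """Encode a junction as a two-block BED12 with ``anchor``-nt flanks.

    The two blocks sit on the exonic sides of the intron; a left anchor
    reaching past the chromosome start is clamped at 0 and shrunk.
    """
    if anchor < 1:
        raise ValueError(f"anchor must be >= 1, got {anchor}")
    chrom_start = max(0, j.donor_end - anchor)
    left_size = j.donor_end - chrom_start
    chrom_end = j.acceptor_start + anchor
    return Bed12Record(
        chrom=j.chrom,
        chromStart=chrom_start,
        chromEnd=chrom_end,
        name=f"SJ|{j.support}",
        score=min(j.support, 1000),
        strand=j.strand,
        thickStart=chrom_start,
        thickEnd=chrom_end,
        itemRgb="0",
        blockCount=2,
        blockSizes=(left_size, anchor),
        blockStarts=(0, j.acceptor_start - chrom_start),
    )


def introns_from_bed12(records) -> list:
    """Annotated introns as the gaps between consecutive BED12 blocks."""
    introns = []
    for rec in records:
        blocks = rec.block_intervals()
        for (_, left_end), (right_start, _) in zip(blocks, blocks[1:]):
            introns.append(GenomicInterval(rec.chrom, left_end, right_start, rec.strand))
    return introns


def classify_junctions(junctions, annotated_introns, tolerance: int = 0):
    """Partition junctions into (known, novel) against annotated introns.

    A junction is known iff its (chrom, donor_end, acceptor_start, strand)
    matches an annotated intron exactly, or within ±``tolerance`` nt on
    each boundary when a tolerance is given.
    """
    exact = {(iv.chrom, iv.start, iv.end, iv.strand) for iv in annotated_introns}
    by_strand: dict = {}
    for iv in annotated_introns:
        by_strand.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    known, novel = [], []
    for j in junctions:
        if j.key in exact:
            known.append(j)
        elif tolerance > 0 and any(
            abs(s - j.donor_end) <= tolerance and abs(e - j.acceptor_start) <= tolerance
            for s, e in by_strand.get((j.chrom, j.strand), ())
        ):
            known.append(j)
        else:
            novel.append(j)
    return known, novel


def splice_site_motifs(junctions, genome_fasta) -> list:
    """Donor/acceptor dinucleotides and canonical (GT..AG) flag per junction.

    Returns a list of dicts with keys junction, donor, acceptor,
    canonical, in_bounds. Junctions reaching past the sequence get motif
    ``NN`` and ``in_bounds=False``.
    """
    fa = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(str(genome_fasta))
    out = []
    for j in junctions:
        if j.chrom not in fa:
            raise KeyError(f"junction chrom {j.chrom!r} absent from genome")
        seq = fa[j.chrom]
        in_bounds = j.donor_end + 2 <= len(seq) and j.acceptor_start - 2 >= 0
        if not in_bounds:
            donor = acceptor = "NN"
        else:
            five = str(seq[j.donor_end : j.donor_end + 2]).upper()
            three = str(seq[j.acceptor_start - 2 : j.acceptor_start]).upper()
            if j.strand == "-":
                donor, acceptor = _revcomp(three), _revcomp(five)
            else:
                donor, acceptor = five, three
        out.append(
            {
                "junction": j,
                "donor": donor,
                "acceptor": acceptor,
                "canonical": (donor, acceptor) == ("GT", "AG"),
                "in_bounds": in_bounds,
            }
        )
    return out


def junction_summary_rows(junctions, annotated_introns, genome_fasta, tolerance: int = 0):
    """TSV-ready rows: junction coordinates, support, class, motifs, canonical."""
    known, _ = classify_junctions(junctions, annotated_introns, tolerance)
    known_keys = {j.key for j in known}
    rows = []
    for m in splice_site_motifs(junctions, genome_fasta):
        j = m["junction"]
        rows.append(
            {
                "chrom": j.chrom,
                "donor_end": j.donor_end,
                "acceptor_start": j.acceptor_start,
                "strand": j.strand,
                "support": j.support,
                "class": "known" if j.key in known_keys else "novel",
                "donor": m["donor"],
                "acceptor": m["acceptor"],
                "canonical": int(m["canonical"]),
            }
        )
    return rows
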
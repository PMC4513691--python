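"""Deterministic synthetic-data generator for every format the toolkit reads.

One integer seed drives a single pseudo-random stream; identical spec +
seed reproduces byte-identical files. The generator emits a small genome
(FASTA + chrom.sizes), a gene annotation (GFF3 + BED12, spliced genes get
multi-block records whose introns are forced to GT..AG termini so splice
motif calls have positive controls), a SAM read set covering every
alignment category (single-end, paired, missing-mate, multi-mapped with
NH tags, junction reads with N-gap CIGARs), a segemehl-style junction
BED6, and a ground-truth table of every category count for
parameter-recovery tests.

The generator emulates category structure, not realism: uniform base
composition, fixed-range read qualities, no coverage bias and no
sequencing-error model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats import write_bed, write_chrom_sizes, write_gff3, Gff3Record
from .intervals import Bed12Record

__all__ = ["FixtureSpec", "Genome", "make_genome", "make_annotation", "make_alignments",
           "make_junction_bed6", "write_fixture_set"]

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Shape of one synthetic data set; all randomness flows from ``seed``."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10000
    n_genes: int = 20
    spliced_fraction: float = 0.3
    exons_per_gene: int = 3
    n_reads: int = 500
    read_length: int = 50
    paired_fraction: float = 0.4
    multi_fraction: float = 0.1
    missing_mate_fraction: float = 0.05
    junction_read_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("spliced_fraction", "paired_fraction", "multi_fraction",
                     "missing_mate_fraction", "junction_read_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_reads", "read_length",
                     "exons_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Genome:
    """Mutable synthetic genome: chrom -> list of bases (patchable in place)."""

    seqs: dict

    def sequence(self, chrom: str) -> str:
        return "".join(self.seqs[chrom])

    @property
    def sizes(self) -> dict:
        return {c: len(s) for c, s in self.seqs.items()}

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w", newline="\n") as fh:
            for chrom in self.seqs:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def make_genome(spec: FixtureSpec) -> Genome:
    """Uniform-random ACGT chromosomes named chr1, chr2, ..."""
    rng = np.random.default_rng(spec.seed)
    seqs = {
        f"chr{i + 1}": list(rng.choice(_BASES, size=spec.chrom_length))
        for i in range(spec.n_chroms)
    }
    return Genome(seqs=seqs)


@dataclass
class _Gene:
    name: str
    chrom: str
    strand: str
    exons: list  # [(start, end)] sorted

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list:
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]

    @property
    def spliced(self) -> bool:
        return len(self.exons) > 1


def _patch_intron_motifs(genome: Genome, gene: _Gene) -> None:
    # Donor GT / acceptor AG in transcript orientation; genomic CT..AC on '-'
    for istart, iend in gene.introns:
        seq = genome.seqs[gene.chrom]
        if gene.strand == "-":
            seq[istart], seq[istart + 1] = "C", "T"
            seq[iend - 2], seq[iend - 1] = "A", "C"
        else:
            seq[istart], seq[istart + 1] = "G", "T"
            seq[iend - 2], seq[iend - 1] = "A", "G"


def make_annotation(spec: FixtureSpec, genome: Genome):
    """Place non-overlapping genes; returns (genes, bed12_records, gff3_records).

    Spliced genes receive ``exons_per_gene`` exon blocks with GT..AG
    introns (the genome is patched in place). Raises when the genome
    cannot hold the requested genes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    chroms = list(genome.seqs)
    n_spliced = round(spec.n_genes * spec.spliced_fraction)
    spliced_flags = np.array([True] * n_spliced + [False] * (spec.n_genes - n_spliced))
    rng.shuffle(spliced_flags)

    genes: list = []
    cursors = {c: 100 for c in chroms}
    for gi in range(spec.n_genes):
        chrom = chroms[gi % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursors[chrom]
        if spliced_flags[gi] and spec.exons_per_gene > 1:
            exons = []
            p = pos
            for e in range(spec.exons_per_gene):
                exon_len = int(rng.integers(60, 121))
                exons.append((p, p + exon_len))
                p += exon_len
                if e < spec.exons_per_gene - 1:
                    p += int(rng.integers(60, 121))  # intron
        else:
            exons = [(pos, pos + int(rng.integers(300, 701)))]
        gene = _Gene(name=f"g{gi + 1:04d}", chrom=chrom, strand=strand, exons=exons)
        if gene.end > len(genome.seqs[chrom]) - 100:
            raise ValueError(
                f"genome too small for {spec.n_genes} genes "
                f"(chrom {chrom} exhausted at gene {gene.name})"
            )
        _patch_intron_motifs(genome, gene)
        genes.append(gene)
        cursors[chrom] = gene.end + int(rng.integers(50, 151))

    bed12, gff3 = [], []
    for g in genes:
        bed12.append(
            Bed12Record(
                chrom=g.chrom,
                chromStart=g.start,
                chromEnd=g.end,
                name=g.name,
                score=0,
                strand=g.strand,
                thickStart=g.start,
                thickEnd=g.end,
                itemRgb="0",
                blockCount=len(g.exons),
                blockSizes=tuple(e - s for s, e in g.exons),
                blockStarts=tuple(s - g.start for s, _ in g.exons),
            )
        )
        gff3.append(
            Gff3Record(
                seqid=g.chrom,
                source="fixture",
                type="gene",
                start=g.start + 1,
                end=g.end,
                score=".",
                strand=g.strand,
                phase=".",
                attributes={"ID": g.name, "locus_tag": g.name},
            )
        )
    return genes, bed12, gff3


@dataclass
class GroundTruth:
    """Category counts and per-feature counts realized by make_alignments."""

    total_alignments: int = 0
    aligned_reads: int = 0
    unique_reads: int = 0
    multi_reads: int = 0
    se_reads: int = 0
    pe_pairs: int = 0
    pe_missing_mate: int = 0
    plus_primary: int = 0
    minus_primary: int = 0
    feature_counts: dict = field(default_factory=dict)
    junctions: dict = field(default_factory=dict)  # key -> support

    def as_rows(self):
        rows = [("category", k, v) for k, v in (
            ("total_alignments", self.total_alignments),
            ("aligned_reads", self.aligned_reads),
            ("unique_reads", self.unique_reads),
            ("multi_reads", self.multi_reads),
            ("se_reads", self.se_reads),
            ("pe_pairs", self.pe_pairs),
            ("pe_missing_mate", self.pe_missing_mate),
            ("plus_primary", self.plus_primary),
            ("minus_primary", self.minus_primary),
        )]
        rows += [("feature", k, v) for k, v in sorted(self.feature_counts.items())]
        rows += [
            ("junction", f"{c}:{d}-{a}:{s}", v)
            for (c, d, a, s), v in sorted(self.junctions.items())
        ]
        return rows


def _mutate(rng, seq: str, n_mm: int) -> str:
    seq = list(seq)
    if n_mm > 0:
        for pos in rng.choice(len(seq), size=min(n_mm, len(seq)), replace=False):
            others = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = others[int(rng.integers(0, 3))]
    return "".join(seq)


def _qual(rng, n: int) -> str:
    return "".join(chr(33 + q) for q in rng.integers(30, 41, size=n))


def _sam_line(qname, flag, chrom, pos0, mapq, cigar, seq, qual, tags,
              rnext="*", pnext0=-1, tlen=0):
    fields = [qname, str(flag), chrom, str(pos0 + 1), str(mapq), cigar,
              rnext, str(pnext0 + 1), str(tlen), seq, qual] + tags
    return "\t".join(fields)


def make_alignments(spec: FixtureSpec, genome: Genome, genes):
    """Sample reads from gene bodies; returns (sam_text, GroundTruth).

    Reads are sampled uniformly over genes on the gene's strand. A
    fraction become paired fragments (FR layout, read 1 on the gene
    strand), of which some lose their mate (mate-unmapped flag); among the
    single-end reads a fraction are multi-mapped (NH > 1, one primary plus
    NH-1 secondary records at random decoy positions) and, for spliced
    genes, a fraction span an intron with an N-gap CIGAR. NM tags record
    the mismatches actually introduced.
    """
    rng = np.random.default_rng(spec.seed + 2)
    rl = spec.read_length
    truth = GroundTruth(feature_counts={g.name: 0 for g in genes})
    lines = []
    header = ["@HD\tVN:1.6\tSO:unknown"] + [
        f"@SQ\tSN:{c}\tLN:{n}" for c, n in genome.sizes.items()
    ]

    def read_seq(chrom, segments):
        return "".join(genome.sequence(chrom)[s:e] for s, e in segments)

    def record_primary(gene, strand):
        truth.aligned_reads += 1
        truth.total_alignments += 1
        truth.feature_counts[gene.name] += 1
        if strand == "-":
            truth.minus_primary += 1
        else:
            truth.plus_primary += 1

    eligible_exons = lambda g: [e for e in g.exons if e[1] - e[0] >= rl]

    for i in range(spec.n_reads):
        gene = genes[int(rng.integers(0, len(genes)))]
        chrom = gene.chrom
        qname = f"read{i + 1}"
        paired = rng.random() < spec.paired_fraction

        if paired:
            exons = eligible_exons(gene)
            if not exons:
                paired = False
            else:
                missing = rng.random() < spec.missing_mate_fraction
                e1 = exons[int(rng.integers(0, len(exons)))]
                p1 = int(rng.integers(e1[0], e1[1] - rl + 1))
                rev1 = gene.strand == "-"
                seq1 = read_seq(chrom, [(p1, p1 + rl)])
                nm1 = int(rng.integers(0, 3))
                seq1 = _mutate(rng, seq1, nm1)
                if missing:
                    flag1 = 0x1 | 0x8 | 0x40 | (0x10 if rev1 else 0)
                    lines.append(_sam_line(
                        qname, flag1, chrom, p1, 60, f"{rl}M", seq1, _qual(rng, rl),
                        [f"NM:i:{nm1}", "NH:i:1"], rnext="=", pnext0=p1))
                    record_primary(gene, gene.strand)
                    truth.unique_reads += 1
                    truth.pe_missing_mate += 1
                else:
                    e2 = exons[int(rng.integers(0, len(exons)))]
                    p2 = int(rng.integers(e2[0], e2[1] - rl + 1))
                    seq2 = read_seq(chrom, [(p2, p2 + rl)])
                    nm2 = int(rng.integers(0, 3))
                    seq2 = _mutate(rng, seq2, nm2)
                    # FR layout: read 1 on the gene strand, read 2 opposite
                    if gene.strand == "-":
                        flag1 = 0x1 | 0x2 | 0x10 | 0x40  # 83
                        flag2 = 0x1 | 0x2 | 0x20 | 0x80  # 163
                    else:
                        flag1 = 0x1 | 0x2 | 0x20 | 0x40  # 99
                        flag2 = 0x1 | 0x2 | 0x10 | 0x80  # 147
                    lines.append(_sam_line(
                        qname, flag1, chrom, p1, 60, f"{rl}M", seq1, _qual(rng, rl),
                        [f"NM:i:{nm1}", "NH:i:1"], rnext="=", pnext0=p2))
                    lines.append(_sam_line(
                        qname, flag2, chrom, p2, 60, f"{rl}M", seq2, _qual(rng, rl),
                        [f"NM:i:{nm2}", "NH:i:1"], rnext="=", pnext0=p1))
                    record_primary(gene, gene.strand)
                    record_primary(gene, gene.strand)  # read 2 follows read 1
                    truth.unique_reads += 2
                    truth.pe_pairs += 1
                continue

        rev = gene.strand == "-"
        flag_rev = 0x10 if rev else 0
        junction = (
            gene.spliced
            and rng.random() < spec.junction_read_fraction
        )
        if junction:
            introns = gene.introns
            k = int(rng.integers(0, len(introns)))
            donor, acceptor = introns[k]
            left = gene.exons[k]
            right = gene.exons[k + 1]
            a_min = max(10, rl - (right[1] - right[0]))
            a_max = min(rl - 10, donor - left[0])
            a = int(rng.integers(a_min, a_max + 1))
            b = rl - a
            pos = donor - a
            cigar = f"{a}M{acceptor - donor}N{b}M"
            seq = read_seq(chrom, [(pos, donor), (acceptor, acceptor + b)])
            nm = 0
            lines.append(_sam_line(
                qname, flag_rev, chrom, pos, 60, cigar, seq, _qual(rng, rl),
                [f"NM:i:{nm}", "NH:i:1"]))
            record_primary(gene, gene.strand)
            truth.unique_reads += 1
            truth.se_reads += 1
            jkey = (chrom, donor, acceptor, gene.strand)
            truth.junctions[jkey] = truth.junctions.get(jkey, 0) + 1
            continue

        exons = eligible_exons(gene)
        if not exons:
            exons = [(gene.start, gene.end)]
        e1 = exons[int(rng.integers(0, len(exons)))]
        pos = int(rng.integers(e1[0], e1[1] - rl + 1))
        seq = read_seq(chrom, [(pos, pos + rl)])
        nm = int(rng.integers(0, 3))
        seq = _mutate(rng, seq, nm)
        multi = rng.random() < spec.multi_fraction
        if multi:
            nh = int(rng.integers(2, 4))
            lines.append(_sam_line(
                qname, flag_rev, chrom, pos, 1, f"{rl}M", seq, _qual(rng, rl),
                [f"NM:i:{nm}", f"NH:i:{nh}"]))
            record_primary(gene, gene.strand)
            truth.multi_reads += 1
            truth.se_reads += 1
            for _ in range(nh - 1):
                dchrom = list(genome.seqs)[int(rng.integers(0, len(genome.seqs)))]
                dpos = int(rng.integers(0, len(genome.seqs[dchrom]) - rl))
                lines.append(_sam_line(
                    qname, flag_rev | 0x100, dchrom, dpos, 0, f"{rl}M", seq,
                    _qual(rng, rl), ["NM:i:0", f"NH:i:{nh}"]))
                truth.total_alignments += 1
        else:
            lines.append(_sam_line(
                qname, flag_rev, chrom, pos, 60, f"{rl}M", seq, _qual(rng, rl),
                [f"NM:i:{nm}", "NH:i:1"]))
            record_primary(gene, gene.strand)
            truth.unique_reads += 1
            truth.se_reads += 1

    sam_text = "\n".join(header + lines) + "\n"
    return sam_text, truth


def make_junction_bed6(junctions: dict, path, jitter: int = 0) -> None:
    """Write junctions as segemehl-dialect BED6 (interval spans the intron).

    ``junctions`` maps (chrom, donor_end, acceptor_start, strand) ->
    support. A non-zero ``jitter`` shifts both intron boundaries by that
    many nt, producing junctions that match no annotated intron.
    """
    with open(path, "w", newline="\n") as fh:
        for (chrom, donor, acceptor, strand), support in sorted(junctions.items()):
            d, a = donor + jitter, acceptor + jitter
            name = f"splits:{support}:{support}:{support}:N:P"
            fh.write(f"{chrom}\t{d}\t{a}\t{name}\t0\t{strand}\n")


def write_fixture_set(spec: FixtureSpec, out_dir) -> dict:
    """Generate and write the full fixture directory; returns paths + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(spec)
    genes, bed12, gff3 = make_annotation(spec, genome)
    sam_text, truth = make_alignments(spec, genome, genes)

    paths = {
        "fasta": out / "genome.fa",
        "chrom_sizes": out / "genome.chrom.sizes",
        "gff3": out / "annotation.gff3",
        "bed12": out / "annotation.bed12",
        "sam": out / "reads.sam",
        "junction_bed": out / "junctions.bed",
        "ground_truth": out / "ground_truth.tsv",
    }
    genome.write_fasta(paths["fasta"])
    write_chrom_sizes(genome.sizes, paths["chrom_sizes"])
    write_gff3(gff3, paths["gff3"])
    write_bed(bed12, paths["bed12"])
    paths["sam"].write_text(sam_text)
    make_junction_bed6(truth.junctions, paths["junction_bed"])
    with open(paths["ground_truth"], "w", newline="\n") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["kind", "key", "value"])
        w.writerows(truth.as_rows())
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth,
            "genome": genome, "genes": genes, "bed12": bed12, "gff3": gff3}
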
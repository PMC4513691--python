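"""Small sequence utilities: k-mer counting, FastQ trimming, MEME XML summaries."""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from lxml import etree

__all__ = [
    "KmerCounts",
    "MotifSummary",
    "count_kmers",
    "count_kmers_in_file",
    "trim_fastq",
    "trim_fastq_file",
    "extract_meme_motifs",
    "meme_aggregates",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class KmerCounts:
    """Sliding-window k-mer occurrence counts (stride 1, case-folded)."""

    k: int
    counts: Counter = field(default_factory=Counter)
    total_windows: int = 0

    def frequencies(self) -> dict:
        if self.total_windows == 0:
            return {}
        return {kmer: n / self.total_windows for kmer, n in self.counts.items()}


def count_kmers(sequences, k: int, canonical: bool = False) -> KmerCounts:
    """Count k-mers over an iterable of sequences.

    Windows containing non-ACGT symbols are counted under their literal
    (upper-cased) key; sequences shorter than k contribute nothing. With
    ``canonical`` each window is merged with its reverse complement under
    the lexicographically smaller key.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    kc = KmerCounts(k=k)
    for seq in sequences:
        seq = str(seq).upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if canonical:
                rc = kmer.translate(_COMPLEMENT)[::-1]
                kmer = min(kmer, rc)
            kc.counts[kmer] += 1
            kc.total_windows += 1
    return kc


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    with _open_maybe_gz(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def count_kmers_in_file(path, k: int, canonical: bool = False) -> KmerCounts:
    """Count k-mers in a FASTA or FastQ file (gz-transparent, auto-detected)."""
    fmt = _sniff_format(path)
    with _open_maybe_gz(path) as fh:
        return count_kmers((str(rec.seq) for rec in SeqIO.parse(fh, fmt)), k, canonical)


def trim_fastq(record, trim5: int = 0, trim3: int = 0):
    """Trim a FastQ ``(id, seq, qual)`` record identically in seq and qual.

    Returns the trimmed record, or None when trimming consumes the whole
    read (the record is dropped).
    """
    rid, seq, qual = record
    if len(seq) != len(qual):
        raise ValueError(f"record {rid!r}: seq length {len(seq)} != qual length {len(qual)}")
    if trim5 < 0 or trim3 < 0:
        raise ValueError("trim5 and trim3 must be non-negative")
    if trim5 + trim3 >= len(seq):
        return None
    end = len(seq) - trim3
    return (rid, seq[trim5:end], qual[trim5:end])


def trim_fastq_file(in_path, out_path, trim5: int = 0, trim3: int = 0):
    """Trim every record of a FastQ file; returns (kept, dropped) counts."""
    kept = dropped = 0
    with _open_maybe_gz(in_path) as fh, open(out_path, "w", newline="\n") as out:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and len(seq) != 0:
                raise ValueError(f"truncated FastQ record at {header.strip()!r}")
            rid = header.strip()[1:]
            trimmed = trim_fastq((rid, seq, qual), trim5, trim3)
            if trimmed is None:
                dropped += 1
                continue
            _, tseq, tqual = trimmed
            out.write(f"@{rid}\n{tseq}\n{plus.strip() or '+'}\n{tqual}\n")
            kept += 1
    return kept, dropped


@dataclass(frozen=True)
class MotifSummary:
    motif_id: str
    width: int
    evalue: float
    n_sites: int
    consensus: str

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("motif width must be >= 1")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")


def extract_meme_motifs(xml_path) -> list:
    """Parse MEME-suite XML into one MotifSummary per motif, file order kept.

    Reads the ``id``, ``width``, ``sites`` and ``e_value`` attributes of
    each ``<motif>`` element; the consensus is the motif ``name`` (MEME
    writes the consensus there) or the ``id`` as fallback.
    """
    tree = etree.parse(str(xml_path))
    out = []
    for motif in tree.iter("motif"):
        attrs = motif.attrib
        out.append(
            MotifSummary(
                motif_id=attrs.get("id", attrs.get("name", "?")),
                width=int(attrs["width"]),
                evalue=float(attrs.get("e_value", attrs.get("evalue", "nan"))),
                n_sites=int(attrs.get("sites", 0)),
                consensus=attrs.get("name", attrs.get("id", "?")),
            )
        )
    return out


def meme_aggregates(motifs) -> dict:
    """Aggregate statistics over a motif list: counts, sites, best e-value."""
    agg = {
        "n_motifs": len(motifs),
        "total_sites": sum(m.n_sites for m in motifs),
        "sites_per_motif": {m.motif_id: m.n_sites for m in motifs},
    }
    if motifs:
        agg["best_evalue"] = min(m.evalue for m in motifs)
    return agg
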
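"""Mapping statistics from SAM/BAM files and multi-sample CSV summaries.

Quantitative side: total alignment records, aligned reads (each mate of a
pair counts as a read), unique vs multi-mapped reads, and the single-end /
paired / missing-mate breakdown. Qualitative side: per-alignment edit
distance (NM tag), clipped-base fraction, matched-base fraction and mean
base quality, each kept both as a mean and as a histogram.

Uniqueness is decided by the NH tag where present (NH == 1 means unique);
files without NH fall back to a name-collated pass that counts reported
alignments per read.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam

__all__ = ["AlignmentStats", "collect_stats", "summarize_samples", "write_summary_csv"]

# CIGAR operation codes (pysam numeric encoding)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_EQ, _OP_X = 0, 1, 2, 3, 4, 5, 7, 8
_READ_LEN_OPS = {_OP_M, _OP_I, _OP_S, _OP_H, _OP_EQ, _OP_X}
_MATCH_OPS = {_OP_M, _OP_EQ, _OP_X}
_CLIP_OPS = {_OP_S, _OP_H}


@dataclass
class AlignmentStats:
    """Aggregated per-sample mapping statistics."""

    total_alignments: int = 0
    aligned_reads: int = 0
    unique_reads: int = 0
    multi_reads: int = 0
    se_reads: int = 0
    pe_pairs: int = 0
    pe_missing_mate: int = 0
    edit_distances: Counter = field(default_factory=Counter)
    nm_unknown: int = 0
    clip_hist: Counter = field(default_factory=Counter)  # fraction rounded to 0.01
    match_hist: Counter = field(default_factory=Counter)
    quality_hist: Counter = field(default_factory=Counter)  # mean Phred, rounded int
    mapq_hist: Counter = field(default_factory=Counter)
    clip_sum: float = 0.0
    match_sum: float = 0.0
    quality_sum: float = 0.0
    quality_n: int = 0

    @property
    def mean_clip_fraction(self) -> float:
        return self.clip_sum / self.aligned_reads if self.aligned_reads else 0.0

    @property
    def mean_match_fraction(self) -> float:
        return self.match_sum / self.aligned_reads if self.aligned_reads else 0.0

    @property
    def mean_quality(self) -> float:
        return self.quality_sum / self.quality_n if self.quality_n else 0.0

    def validate(self) -> None:
        assert self.unique_reads + self.multi_reads == self.aligned_reads
        assert self.total_alignments >= self.aligned_reads


def _open_alignment(path):
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    af = pysam.AlignmentFile(path, mode, check_sq=False)
    if not af.header.to_dict().get("SQ") and not path.endswith(".bam"):
        # SAM without any @SQ line cannot anchor coordinates
        af.close()
        raise ValueError(f"{path}: missing header (@SQ lines required)")
    return af


def _cigar_fractions(aln):
    """(clip_fraction, match_fraction) from the CIGAR, hard clips included."""
    cig = aln.cigartuples
    if not cig:
        return 0.0, 0.0
    read_len = sum(n for op, n in cig if op in _READ_LEN_OPS)
    if read_len == 0:
        return 0.0, 0.0
    clip = sum(n for op, n in cig if op in _CLIP_OPS)
    match = sum(n for op, n in cig if op in _MATCH_OPS)
    return clip / read_len, match / read_len


def _multi_read_keys(path) -> set:
    """Name-collation fallback: keys of reads with >1 reported alignment."""
    counts: Counter = Counter()
    with _open_alignment(path) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_supplementary:
                continue
            counts[(aln.query_name, aln.is_read2)] += 1
    return {k for k, n in counts.items() if n > 1}


def collect_stats(path) -> AlignmentStats:
    """Compute :class:`AlignmentStats` over one SAM/BAM file.

    Read-level counts use primary alignments only; ``total_alignments``
    counts every mapped record including secondary and supplementary.
    """
    stats = AlignmentStats()
    nh_seen = True
    pe_mates: dict = {}  # qname -> set of mates seen mapped with mate mapped
    fallback_multi: set | None = None

    with _open_alignment(path) as af:
        for aln in af:
            if aln.is_unmapped:
                continue
            stats.total_alignments += 1
            if aln.is_secondary or aln.is_supplementary:
                continue

            stats.aligned_reads += 1
            nh = aln.get_tag("NH") if aln.has_tag("NH") else None
            if nh is None:
                nh_seen = False
            elif nh == 1:
                stats.unique_reads += 1
            else:
                stats.multi_reads += 1

            if not aln.is_paired:
                stats.se_reads += 1
            elif aln.mate_is_unmapped:
                stats.pe_missing_mate += 1
            else:
                pe_mates.setdefault(aln.query_name, set()).add(aln.is_read2)

            if aln.has_tag("NM"):
                stats.edit_distances[int(aln.get_tag("NM"))] += 1
            else:
                stats.nm_unknown += 1

            clip, match = _cigar_fractions(aln)
            stats.clip_sum += clip
            stats.match_sum += match
            stats.clip_hist[round(clip, 2)] += 1
            stats.match_hist[round(match, 2)] += 1
            quals = aln.query_qualities
            if quals is not None and len(quals) > 0:
                mean_q = sum(quals) / len(quals)
                stats.quality_sum += mean_q
                stats.quality_n += 1
                stats.quality_hist[round(mean_q)] += 1
            stats.mapq_hist[aln.mapping_quality] += 1

    for mates in pe_mates.values():
        if len(mates) == 2:
            stats.pe_pairs += 1
        else:
            # mate flagged mapped but its record is absent from the file
            stats.pe_missing_mate += len(mates)

    if not nh_seen:
        # second pass: classify by reported-alignment multiplicity
        stats.unique_reads = stats.multi_reads = 0
        multi = _multi_read_keys(path)
        with _open_alignment(path) as af:
            for aln in af:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if (aln.query_name, aln.is_read2) in multi:
                    stats.multi_reads += 1
                else:
                    stats.unique_reads += 1

    stats.validate()
    return stats


_CSV_COLUMNS = [
    "sample",
    "total_alignments",
    "aligned_reads",
    "unique_reads",
    "multi_reads",
    "se_reads",
    "pe_pairs",
    "pe_missing_mate",
    "mean_edit_distance",
    "mean_clip_fraction",
    "mean_match_fraction",
    "mean_base_quality",
]


def summarize_samples(samples) -> str:
    """Render per-sample statistics as an RFC-4180 CSV string.

    Parameters
    ----------
    samples : list of (name, AlignmentStats)
        At least one sample; names must be unique.
    """
    if not samples:
        raise ValueError("need at least one sample")
    names = [name for name, _ in samples]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate sample names: {sorted(names)}")
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    for name, st in samples:
        nm_total = sum(st.edit_distances.values())
        mean_nm = (
            sum(d * n for d, n in st.edit_distances.items()) / nm_total if nm_total else 0.0
        )
        writer.writerow(
            [
                name,
                st.total_alignments,
                st.aligned_reads,
                st.unique_reads,
                st.multi_reads,
                st.se_reads,
                st.pe_pairs,
                st.pe_missing_mate,
                f"{mean_nm:.4f}",
                f"{st.mean_clip_fraction:.4f}",
                f"{st.mean_match_fraction:.4f}",
                f"{st.mean_quality:.4f}",
            ]
        )
    return buf.getvalue()


def write_summary_csv(samples, path) -> None:
    Path(path).write_text(summarize_samples(samples))


def plot_summary(samples, out_dir) -> list:
    """Optional graphical layer over the CSV: bar charts per statistic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [name for name, _ in samples]
    written = []
    panels = {
        "aligned_reads": [st.aligned_reads for _, st in samples],
        "unique_vs_multi": None,
        "mean_clip_fraction": [st.mean_clip_fraction for _, st in samples],
        "mean_match_fraction": [st.mean_match_fraction for _, st in samples],
    }
    for key, values in panels.items():
        fig, ax = plt.subplots(figsize=(4, 3))
        if key == "unique_vs_multi":
            uniq = [st.unique_reads for _, st in samples]
            multi = [st.multi_reads for _, st in samples]
            ax.bar(names, uniq, label="unique")
            ax.bar(names, multi, bottom=uniq, label="multi")
            ax.legend()
        else:
            ax.bar(names, values)
        ax.set_title(key)
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        out = out_dir / f"{key}.png"
        fig.savefig(out)
        plt.close(fig)
        written.append(out)
    return written
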
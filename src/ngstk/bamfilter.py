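"""Alignment-file filtering: strand splitting, unique/multi separation,
coverage profiles.

Paired-end strand convention: fragment strand = strand of read 1 (FR
library layout); ``library_type="rf"`` flips it. Coverage counts reference
bases under M/=/X and D CIGAR operations; N splice gaps and insertions
contribute nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pysam

from .bamstat import _multi_read_keys, _open_alignment
from .formats import BedGraphTrack, _coverage_sweep

__all__ = [
    "SplitResult",
    "split_by_strand",
    "split_unique_multi",
    "coverage_profile",
    "write_bigwig",
]

_COVER_OPS = {0, 2, 7, 8}  # M, D, =, X consume reference and count as covered
_REF_OPS = {0, 2, 3, 7, 8}  # + N: consume reference


@dataclass
class SplitResult:
    plus_path: str
    minus_path: str
    plus_count: int
    minus_count: int


def _fragment_reverse(aln, library_type: str) -> bool:
    """True if the fragment maps to the minus strand under the library layout."""
    rev = aln.is_reverse
    if aln.is_paired and aln.is_read2:
        rev = not rev  # read 2 reports the opposite strand of its fragment
    if library_type == "rf":
        rev = not rev
    return rev


def _out_path(prefix, tag, like_path) -> str:
    ext = ".bam" if str(like_path).endswith(".bam") else ".sam"
    return f"{prefix}.{tag}{ext}"


def _writer(path, template):
    mode = "wb" if path.endswith(".bam") else "wh"
    return pysam.AlignmentFile(path, mode, template=template)


def split_by_strand(path, out_prefix, library_type: str = "fr") -> SplitResult:
    """Split an alignment file into (+) and (-) strand files.

    Headers are copied; unmapped reads are dropped; secondary and
    supplementary records follow the same routing rule as primaries but
    only primaries are counted.
    """
    if library_type not in ("fr", "rf"):
        raise ValueError(f"library_type must be 'fr' or 'rf', got {library_type!r}")
    plus_path = _out_path(out_prefix, "plus", path)
    minus_path = _out_path(out_prefix, "minus", path)
    plus_count = minus_count = 0
    with _open_alignment(path) as af:
        with _writer(plus_path, af) as plus_fh, _writer(minus_path, af) as minus_fh:
            for aln in af:
                if aln.is_unmapped:
                    continue
                primary = not (aln.is_secondary or aln.is_supplementary)
                if _fragment_reverse(aln, library_type):
                    minus_fh.write(aln)
                    minus_count += primary
                else:
                    plus_fh.write(aln)
                    plus_count += primary
    return SplitResult(plus_path, minus_path, plus_count, minus_count)


def split_unique_multi(path, out_prefix):
    """Separate uniquely from multi-mapped reads.

    All alignment records of a multi-mapped read (primary and secondary)
    go to the multi file. Returns
    ``(unique_path, multi_path, unique_count, multi_count)`` where counts
    are alignment records written.
    """
    unique_path = _out_path(out_prefix, "uniq", path)
    multi_path = _out_path(out_prefix, "mult", path)
    unique_count = multi_count = 0

    # Determine whether NH is available on every mapped record
    nh_everywhere = True
    with _open_alignment(path) as af:
        for aln in af:
            if not aln.is_unmapped and not aln.has_tag("NH"):
                nh_everywhere = False
                break
    multi_keys = None if nh_everywhere else _multi_read_keys(path)

    with _open_alignment(path) as af:
        with _writer(unique_path, af) as uniq_fh, _writer(multi_path, af) as multi_fh:
            for aln in af:
                if aln.is_unmapped:
                    continue
                if nh_everywhere:
                    is_multi = aln.get_tag("NH") > 1
                else:
                    is_multi = (aln.query_name, aln.is_read2) in multi_keys
                if is_multi:
                    multi_fh.write(aln)
                    multi_count += 1
                else:
                    uniq_fh.write(aln)
                    unique_count += 1
    return unique_path, multi_path, unique_count, multi_count


def _covered_segments(aln):
    """Reference [start, end) runs covered by M/=/X/D, split at N gaps."""
    segs = []
    pos = aln.reference_start
    run_start = None
    for op, n in aln.cigartuples or ():
        if op in _COVER_OPS:
            if run_start is None:
                run_start = pos
            pos += n
        elif op in _REF_OPS:  # N gap: close the current run
            if run_start is not None:
                segs.append((run_start, pos))
                run_start = None
            pos += n
    if run_start is not None:
        segs.append((run_start, pos))
    return segs


def coverage_profile(path, strand_specific: bool = False, scale=None, library_type="fr"):
    """Per-base read-depth BedGraph track(s) from an alignment file.

    Depth counts primary alignments only. ``scale`` multiplies every value
    (e.g. reads-per-million scaling with ``scale = 1e6 / mapped_reads``).
    With ``strand_specific`` two tracks (+ then -) are returned.
    """
    if scale is not None and scale <= 0:
        raise ValueError("scale must be positive")
    plus_ivs, minus_ivs = [], []
    with _open_alignment(path) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            bucket = (
                minus_ivs
                if strand_specific and _fragment_reverse(aln, library_type)
                else plus_ivs
            )
            chrom = aln.reference_name
            bucket.extend((chrom, s, e) for s, e in _covered_segments(aln))

    def _track(ivs, strand=None):
        lines = _coverage_sweep(ivs)
        if scale is not None:
            lines = [(c, s, e, v * scale) for c, s, e, v in lines]
        return BedGraphTrack(lines=lines, strand=strand)

    if strand_specific:
        return _track(plus_ivs, "+"), _track(minus_ivs, "-")
    return _track(plus_ivs)


def write_bigwig(track: BedGraphTrack, chrom_sizes: dict, path) -> bool:
    """Encode a BedGraph track as BigWig via pyBigWig if it is importable.

    Returns True on success, False when no encoder is available (the
    BedGraph text remains the deliverable).
    """
    try:
        import pyBigWig
    except ImportError:
        warnings.warn("pyBigWig not available; BedGraph text is the deliverable")
        return False
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(sorted(chrom_sizes.items()))
    for chrom, start, end, value in track.lines:
        bw.addEntries([chrom], [start], ends=[end], values=[float(value)])
    bw.close()
    return True
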
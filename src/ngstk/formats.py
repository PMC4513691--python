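"""Readers, writers and converters for BED4/6/12, GFF3/GTF, BedGraph.

All in-memory coordinates are 0-based half-open; GFF3's 1-based closed
coordinates are shifted at this I/O boundary and nowhere else.

Includes the bacterial-annotation GFF3 -> BED12 converter (single-block,
non-spliced semantics) and strand-specific BED -> BedGraph coverage
conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .intervals import Bed12Record, ScoredFeature

__all__ = [
    "Gff3Record",
    "BedGraphTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "gff3_to_bed12",
    "bed_to_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

DEFAULT_GFF_KEEP_TYPES = frozenset({"gene", "tRNA", "rRNA", "ncRNA"})


class BedParseError(ValueError):
    """Malformed BED/BedGraph/GFF3 input; message carries the line number."""


@dataclass(frozen=True)
class Gff3Record:
    """One GFF3 feature line, 1-based closed coordinates as in the file."""

    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    score: str
    strand: str
    phase: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise BedParseError(
                f"GFF3 requires 1 <= start <= end, got {self.start}..{self.end}"
            )


@dataclass
class BedGraphTrack:
    """Sparse per-base signal: ordered (chrom, start, end, value) lines.

    Intervals per chrom are sorted and non-overlapping; consecutive
    equal-value runs are merged; zero-coverage regions are omitted.
    """

    lines: list = field(default_factory=list)
    strand: str | None = None

    def total_signal(self) -> float:
        """Sum of (end - start) * value over all lines."""
        return sum((e - s) * v for _, s, e, v in self.lines)

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)


def _fmt_score(score) -> str:
    # BED files conventionally print integral scores without a decimal point
    f = float(score)
    return str(int(f)) if f == int(f) else repr(f)


def read_bed(path) -> list:
    """Read a BED4, BED6 or BED12 file (dialect auto-detected, uniform).

    BED4 yields :class:`ScoredFeature` with score 0 and strand ``.``;
    BED6 yields :class:`ScoredFeature`; BED12 yields :class:`Bed12Record`.
    ``track``/``browser``/``#`` lines are skipped.
    """
    out: list = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if ncols is None:
                ncols = len(fields)
                if ncols not in (4, 6, 12):
                    raise BedParseError(
                        f"{path}:{lineno}: expected 4, 6 or 12 columns, got {ncols}"
                    )
            elif len(fields) != ncols:
                raise BedParseError(
                    f"{path}:{lineno}: mixed column counts ({len(fields)} vs {ncols})"
                )
            try:
                out.append(_parse_bed_fields(fields, ncols))
            except (ValueError, BedParseError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def _parse_bed_fields(fields, ncols):
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    if ncols == 4:
        return ScoredFeature(chrom, start, end, ".", name=fields[3], score=0)
    if ncols == 6:
        return ScoredFeature(
            chrom, start, end, fields[5], name=fields[3], score=float(fields[4])
        )
    return Bed12Record(
        chrom=chrom,
        chromStart=start,
        chromEnd=end,
        name=fields[3],
        score=float(fields[4]),
        strand=fields[5],
        thickStart=int(fields[6]),
        thickEnd=int(fields[7]),
        itemRgb=fields[8],
        blockCount=int(fields[9]),
        blockSizes=[int(x) for x in fields[10].rstrip(",").split(",")],
        blockStarts=[int(x) for x in fields[11].rstrip(",").split(",")],
    )


def _bed_line(obj) -> str:
    if isinstance(obj, Bed12Record):
        return "\t".join(
            [
                obj.chrom,
                str(obj.chromStart),
                str(obj.chromEnd),
                obj.name,
                _fmt_score(obj.score),
                obj.strand,
                str(obj.thickStart),
                str(obj.thickEnd),
                obj.itemRgb,
                str(obj.blockCount),
                ",".join(str(z) for z in obj.blockSizes),
                ",".join(str(s) for s in obj.blockStarts),
            ]
        )
    return "\t".join(
        [obj.chrom, str(obj.start), str(obj.end), obj.name, _fmt_score(obj.score), obj.strand]
    )


def write_bed(objects, path) -> None:
    """Write ScoredFeatures as BED6 / Bed12Records as BED12, tab-separated, LF."""
    with open(path, "w", newline="\n") as fh:
        for obj in objects:
            fh.write(_bed_line(obj) + "\n")


def _parse_gff3_attributes(text: str) -> dict:
    attrs: dict = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
        elif " " in part:  # GTF dialect: key "value"
            key, _, value = part.partition(" ")
            attrs[key.strip()] = value.strip().strip('"')
    return attrs


def read_gff3(path) -> list:
    """Read GFF3 (or GTF: quoted-attribute dialect) into Gff3Records."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise BedParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            try:
                out.append(
                    Gff3Record(
                        seqid=fields[0],
                        source=fields[1],
                        type=fields[2],
                        start=int(fields[3]),
                        end=int(fields[4]),
                        score=fields[5],
                        strand=fields[6],
                        phase=fields[7],
                        attributes=_parse_gff3_attributes(fields[8]),
                    )
                )
            except (ValueError, BedParseError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gff3(records, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(f"{k}={v}" for k, v in r.attributes.items())
            fh.write(
                "\t".join(
                    [
                        r.seqid,
                        r.source,
                        r.type,
                        str(r.start),
                        str(r.end),
                        r.score,
                        r.strand,
                        r.phase,
                        attrs,
                    ]
                )
                + "\n"
            )


def gff3_to_bed12(records, keep_types=DEFAULT_GFF_KEEP_TYPES) -> list:
    """Convert non-spliced GFF3 features to single-block BED12 records.

    Intended for bacterial RefSeq annotation where genes have no exon
    substructure. Name precedence: ``locus_tag`` > ``Name`` > ``ID``;
    features lacking all three are skipped with a warning.
    """
    if not keep_types:
        raise ValueError("keep_types must be non-empty")
    out = []
    for rec in records:
        if rec.type not in keep_types:
            continue
        name = (
            rec.attributes.get("locus_tag")
            or rec.attributes.get("Name")
            or rec.attributes.get("ID")
        )
        if not name:
            warnings.warn(
                f"skipping {rec.type} at {rec.seqid}:{rec.start}..{rec.end}: "
                "no locus_tag/Name/ID attribute"
            )
            continue
        start = rec.start - 1  # 1-based closed -> 0-based half-open
        end = rec.end
        try:
            score = float(rec.score)
        except ValueError:
            score = 0
        out.append(
            Bed12Record(
                chrom=rec.seqid,
                chromStart=start,
                chromEnd=end,
                name=name,
                score=score,
                strand=rec.strand if rec.strand in ("+", "-") else ".",
                thickStart=start,
                thickEnd=end,
                itemRgb="0",
                blockCount=1,
                blockSizes=(end - start,),
                blockStarts=(0,),
            )
        )
    return out


def _coverage_sweep(intervals):
    """Run-length-merged coverage of (chrom, start, end) intervals.

    Boundary-event sweep: O(n log n) in the number of intervals, exact
    per-base counts.
    """
    by_chrom: dict = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, 1))
        by_chrom[chrom].append((end, -1))
    lines = []
    for chrom in sorted(by_chrom):
        events = sorted(by_chrom[chrom])
        segments = []  # (start, end, depth) runs with depth > 0
        depth = 0
        prev_pos = events[0][0]
        for pos, delta in events:
            if pos > prev_pos and depth > 0:
                segments.append([prev_pos, pos, depth])
            depth += delta
            prev_pos = pos
        merged = []
        for seg in segments:
            if merged and merged[-1][1] == seg[0] and merged[-1][2] == seg[2]:
                merged[-1][1] = seg[1]
            else:
                merged.append(seg)
        lines.extend((chrom, s, e, d) for s, e, d in merged)
    return lines


def bed_to_bedgraph(features, strand_specific: bool = False):
    """Coverage of BED features as BedGraph: value = #intervals covering a base.

    With ``strand_specific`` the input is partitioned by strand first and a
    ``(+)`` and a ``(-)`` track are returned; ``.`` intervals go to ``(+)``
    with a warning.
    """
    if not strand_specific:
        return BedGraphTrack(
            lines=_coverage_sweep((f.chrom, f.start, f.end) for f in features)
        )
    plus, minus = [], []
    for f in features:
        if f.strand == "-":
            minus.append(f)
        else:
            if f.strand == ".":
                warnings.warn(
                    f"unstranded interval {f.chrom}:{f.start}-{f.end} assigned to (+) track"
                )
            plus.append(f)
    return (
        BedGraphTrack(
            lines=_coverage_sweep((f.chrom, f.start, f.end) for f in plus), strand="+"
        ),
        BedGraphTrack(
            lines=_coverage_sweep((f.chrom, f.start, f.end) for f in minus), strand="-"
        ),
    )


def write_bedgraph(track: BedGraphTrack, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom, start, end, value in track.lines:
            v = float(value)
            vs = str(int(v)) if v == int(v) else f"{v:g}"
            fh.write(f"{chrom}\t{start}\t{end}\t{vs}\n")


def read_chrom_sizes(path) -> dict:
    """Read UCSC chrom.sizes (two tab-separated columns: name, length)."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
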
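"""Genomic interval data model.

A four-level hierarchy of genomic features, all in 0-based half-open
(BED) coordinates:

* :class:`GenomicInterval` — the elementary interval (chrom, start, end,
  strand).
* :class:`ScoredFeature` — adds a name and a score, i.e. one BED6 element.
* :class:`FeatureChain` — an ordered, non-overlapping run of features
  sharing chrom and strand, e.g. the exon chain of one transcript.
* :class:`FeatureLine` — a transcript-level aggregate mapping role labels
  (``exon``, ``intron``, ``SJ`` ...) to lists of chains.

Conversions to and from BED12 block structure live here because the block
arithmetic is part of the data model, not of file I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomicInterval",
    "ScoredFeature",
    "FeatureChain",
    "FeatureLine",
    "Bed12Record",
    "InvariantError",
    "extend_interval",
    "chain_to_bed12",
    "bed12_to_chain",
    "sort_and_validate_chain",
]

STRANDS = ("+", "-", ".")


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


@dataclass(frozen=True)
class GenomicInterval:
    """An elementary genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Sequence identifier.
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvariantError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise InvariantError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise InvariantError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ScoredFeature(GenomicInterval):
    """A named, scored interval — one BED6 element."""

    name: str = "feature"
    score: float = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if "\t" in self.name:
            raise InvariantError("feature name must not contain tabs")
        if not self.name.strip():
            raise InvariantError("feature name must be non-empty")
        try:
            s = float(self.score)
        except (TypeError, ValueError):
            raise InvariantError(f"score must be numeric, got {self.score!r}")
        if not (0 <= s <= 1000):
            # BED nominally caps score at [0, 1000] but real-world files do not
            warnings.warn(
                f"score {self.score} outside [0, 1000]; passed through unmodified",
                stacklevel=3,
            )


@dataclass(frozen=True)
class FeatureChain:
    """An ordered chain of non-overlapping features on one chrom/strand.

    ``chain_type`` is a free-form role label such as ``exon``, ``intron``
    or ``SJ``. Use :func:`sort_and_validate_chain` to build a chain from
    unsorted input.
    """

    features: tuple
    chain_type: str = "exon"

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        if not self.features:
            raise InvariantError("FeatureChain must contain at least one feature")
        first = self.features[0]
        for f in self.features:
            if f.chrom != first.chrom or f.strand != first.strand:
                raise InvariantError(
                    f"chain members must share chrom and strand: "
                    f"{f.chrom}/{f.strand} vs {first.chrom}/{first.strand}"
                )
        for a, b in zip(self.features, self.features[1:]):
            if b.start < a.start:
                raise InvariantError("chain members must be sorted by start")
            if b.start < a.end:
                raise InvariantError(
                    f"chain members overlap: [{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.features[0].chrom

    @property
    def strand(self) -> str:
        return self.features[0].strand

    @property
    def start(self) -> int:
        return self.features[0].start

    @property
    def end(self) -> int:
        return self.features[-1].end

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class FeatureLine:
    """Transcript-level aggregate: role label -> list of FeatureChain.

    Every chain stored under label ``L`` must have ``chain_type == L``.
    """

    chains: dict = field(default_factory=dict)

    def add(self, chain: FeatureChain) -> None:
        self.chains.setdefault(chain.chain_type, []).append(chain)

    def __post_init__(self) -> None:
        for label, chains in self.chains.items():
            for c in chains:
                if c.chain_type != label:
                    raise InvariantError(
                        f"chain of type {c.chain_type!r} stored under label {label!r}"
                    )

    def __getitem__(self, label: str):
        return self.chains[label]

    def __contains__(self, label: str) -> bool:
        return label in self.chains


@dataclass(frozen=True)
class Bed12Record:
    """One BED12 line: an interval with thick region, color and blocks."""

    chrom: str
    chromStart: int
    chromEnd: int
    name: str
    score: float
    strand: str
    thickStart: int
    thickEnd: int
    itemRgb: str
    blockCount: int
    blockSizes: tuple
    blockStarts: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "blockSizes", tuple(int(x) for x in self.blockSizes))
        object.__setattr__(self, "blockStarts", tuple(int(x) for x in self.blockStarts))
        if not (0 <= self.chromStart < self.chromEnd):
            raise InvariantError(
                f"require 0 <= chromStart < chromEnd, got [{self.chromStart}, {self.chromEnd})"
            )
        if self.strand not in STRANDS:
            raise InvariantError(f"bad strand {self.strand!r}")
        if self.blockCount != len(self.blockSizes) or self.blockCount != len(self.blockStarts):
            raise InvariantError(
                f"blockCount {self.blockCount} != len(blockSizes)={len(self.blockSizes)} "
                f"or len(blockStarts)={len(self.blockStarts)}"
            )
        if self.blockCount < 1:
            raise InvariantError("blockCount must be >= 1")
        if self.blockStarts[0] != 0:
            raise InvariantError(f"blockStarts[0] must be 0, got {self.blockStarts[0]}")
        for (s1, z1), (s2, _z2) in zip(
            zip(self.blockStarts, self.blockSizes),
            zip(self.blockStarts[1:], self.blockSizes[1:]),
        ):
            if s2 <= s1:
                raise InvariantError("blockStarts must be strictly ascending")
            if s1 + z1 > s2:
                raise InvariantError(f"blocks overlap at relative offsets {s1}+{z1} > {s2}")
        if any(z < 1 for z in self.blockSizes):
            raise InvariantError("blockSizes must be >= 1")
        if self.chromStart + self.blockStarts[-1] + self.blockSizes[-1] != self.chromEnd:
            raise InvariantError(
                "last block must end at chromEnd: "
                f"{self.chromStart} + {self.blockStarts[-1]} + {self.blockSizes[-1]} "
                f"!= {self.chromEnd}"
            )
        if not (self.chromStart <= self.thickStart <= self.thickEnd <= self.chromEnd):
            raise InvariantError(
                "require chromStart <= thickStart <= thickEnd <= chromEnd, got "
                f"{self.chromStart} <= {self.thickStart} <= {self.thickEnd} <= {self.chromEnd}"
            )

    def block_intervals(self):
        """Absolute [start, end) coordinates of each block."""
        return [
            (self.chromStart + s, self.chromStart + s + z)
            for s, z in zip(self.blockStarts, self.blockSizes)
        ]


def extend_interval(
    iv: GenomicInterval,
    side: str,
    amount: int,
    chrom_length: int,
) -> GenomicInterval:
    """Extend an interval at its 5', 3' or both ends, strand-aware.

    For a ``+`` (or ``.``) feature the 5' end is ``start``; for ``-`` it
    is ``end``. The result is clamped to ``[0, chrom_length]``.

    Parameters
    ----------
    side : {"five_prime", "three_prime", "both"}
    amount : int
        Non-negative number of bases to add per extended side.
    chrom_length : int
        Length of the chromosome; must be >= ``iv.end``.
    """
    if side not in ("five_prime", "three_prime", "both"):
        raise ValueError(f"side must be five_prime/three_prime/both, got {side!r}")
    if amount < 0:
        raise ValueError(f"amount must be non-negative, got {amount}")
    if chrom_length < iv.end:
        raise ValueError(
            f"chrom_length {chrom_length} inconsistent with interval end {iv.end}"
        )
    # "." behaves as "+" so the operation stays deterministic
    minus = iv.strand == "-"
    extend_start = side == "both" or (side == "five_prime") != minus
    extend_end = side == "both" or (side == "three_prime") != minus
    start = max(0, iv.start - amount) if extend_start else iv.start
    end = min(chrom_length, iv.end + amount) if extend_end else iv.end
    return replace(iv, start=start, end=end)


def chain_to_bed12(
    chain: FeatureChain,
    name: str = "chain",
    score: float = 0,
    rgb: str = "0",
) -> Bed12Record:
    """Render a feature chain as a single BED12 record, one block per feature.

    thickStart/thickEnd default to the full span (no CDS annotation).
    """
    start = chain.start
    return Bed12Record(
        chrom=chain.chrom,
        chromStart=start,
        chromEnd=chain.end,
        name=name,
        score=score,
        strand=chain.strand,
        thickStart=start,
        thickEnd=chain.end,
        itemRgb=rgb,
        blockCount=len(chain),
        blockSizes=tuple(len(f) for f in chain.features),
        blockStarts=tuple(f.start - start for f in chain.features),
    )


def bed12_to_chain(rec: Bed12Record, chain_type: str = "exon") -> FeatureChain:
    """Inverse of :func:`chain_to_bed12`: one feature per block."""
    feats = [
        ScoredFeature(
            chrom=rec.chrom,
            start=s,
            end=e,
            strand=rec.strand,
            name=f"{rec.name}.{i + 1}",
            score=rec.score,
        )
        for i, (s, e) in enumerate(rec.block_intervals())
    ]
    return FeatureChain(features=tuple(feats), chain_type=chain_type)


def sort_and_validate_chain(features, chain_type: str = "exon") -> FeatureChain:
    """Sort features by start and build a validated chain.

    Overlapping or mixed-chrom/strand inputs raise rather than being
    silently merged.
    """
    if not features:
        raise InvariantError("cannot build a chain from zero features")
    return FeatureChain(
        features=tuple(sorted(features, key=lambda f: (f.start, f.end))),
        chain_type=chain_type,
    )
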
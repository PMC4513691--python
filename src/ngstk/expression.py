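"""Read counting over genomic features and RPKM/TPM normalization.

RPKM (reads per kilobase per million mapped reads) divides the raw count
by feature length (kb) and library size (millions):

    RPKM[i, s] = counts[i, s] * 1e9 / (N_s * L_i)

TPM (transcripts per million) first converts counts to per-base read
rates and then normalizes by the *sum of rates*, so each sample column
sums to 1e6:

    rate[i, s] = counts[i, s] / L_i
    TPM[i, s]  = 1e6 * rate[i, s] / sum_j rate[j, s]

The library size N_s defaults to the column sum of counts over the
provided feature set, which keeps the table self-contained; pass
``library_sizes`` to use externally determined totals (the classical
definition based on all mapped reads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .bamstat import _open_alignment
from .bamfilter import _covered_segments, _fragment_reverse
from .intervals import Bed12Record

__all__ = ["CountTable", "count_reads", "compute_rpkm", "compute_tpm", "expression_table"]


def feature_length(feature) -> int:
    """Length in nt: block-sum for BED12 records, span otherwise."""
    if isinstance(feature, Bed12Record):
        return int(sum(feature.blockSizes))
    return len(feature)


@dataclass
class CountTable:
    """Per-feature raw read counts with feature lengths, one column per sample."""

    features: list
    counts: np.ndarray  # shape (n_features, n_samples), non-negative ints
    sample_names: list
    lengths: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.lengths is None:
            self.lengths = np.array([feature_length(f) for f in self.features])
        self.lengths = np.asarray(self.lengths)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts.reshape(-1, 1)
        if self.counts.shape != (len(self.features), len(self.sample_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.sample_names)} samples"
            )
        if np.any(self.lengths < 1):
            raise ValueError("feature lengths must be >= 1 nt")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def feature_names(self) -> list:
        return [getattr(f, "name", str(i)) for i, f in enumerate(self.features)]


def _feature_blocks(feature):
    if isinstance(feature, Bed12Record):
        return feature.block_intervals()
    return [(feature.start, feature.end)]


def count_reads(path, features, stranded: bool = False, library_type: str = "fr") -> np.ndarray:
    """Count primary alignments overlapping each feature by >= 1 aligned base.

    A read overlapping several features increments each of them (no
    fractional assignment); for BED12 features only exonic blocks count.
    With ``stranded``, only reads whose fragment strand matches the
    feature strand are counted.
    """
    trees: dict = {}
    for idx, feat in enumerate(features):
        chrom = getattr(feat, "chrom", None)
        for s, e in _feature_blocks(feat):
            trees.setdefault(chrom, IntervalTree()).addi(s, e, idx)

    counts = np.zeros(len(features), dtype=int)
    with _open_alignment(path) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            tree = trees.get(aln.reference_name)
            if tree is None:
                continue
            hits = set()
            for s, e in _covered_segments(aln):
                for iv in tree.overlap(s, e):
                    hits.add(iv.data)
            if stranded and hits:
                read_strand = "-" if _fragment_reverse(aln, library_type) else "+"
                hits = {i for i in hits if features[i].strand == read_strand}
            for i in hits:
                counts[i] += 1
    return counts


def compute_rpkm(table: CountTable, library_sizes=None) -> np.ndarray:
    """RPKM matrix; a zero library size yields an all-zero column with a warning."""
    counts = table.counts.astype(float)
    if library_sizes is None:
        n = counts.sum(axis=0)
    else:
        n = np.asarray(library_sizes, dtype=float)
        if n.shape != (counts.shape[1],):
            raise ValueError("library_sizes must have one entry per sample")
    out = np.zeros_like(counts)
    for s in range(counts.shape[1]):
        if n[s] == 0:
            warnings.warn(f"sample {table.sample_names[s]!r} has zero library size; RPKM set to 0")
            continue
        out[:, s] = counts[:, s] * 1e9 / (n[s] * table.lengths)
    return out


def compute_tpm(table: CountTable) -> np.ndarray:
    """TPM matrix; columns sum to 1e6 except all-zero samples (warned, left 0)."""
    rates = table.counts / table.lengths[:, None]
    out = np.zeros_like(rates, dtype=float)
    for s in range(rates.shape[1]):
        total = rates[:, s].sum()
        if total == 0:
            warnings.warn(f"sample {table.sample_names[s]!r} has no counts; TPM set to 0")
            continue
        out[:, s] = 1e6 * rates[:, s] / total
    return out


def expression_table(table: CountTable, library_sizes=None) -> pd.DataFrame:
    """Tidy DataFrame with count, RPKM and TPM columns per sample."""
    rpkm = compute_rpkm(table, library_sizes)
    tpm = compute_tpm(table)
    data = {"feature": table.feature_names, "length": table.lengths}
    for s, name in enumerate(table.sample_names):
        data[f"{name}.count"] = table.counts[:, s]
        data[f"{name}.rpkm"] = rpkm[:, s]
        data[f"{name}.tpm"] = tpm[:, s]
    return pd.DataFrame(data)


def read_count_table(path) -> CountTable:
    """Read a precomputed TSV count table: feature, length, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["feature", "length"]:
        raise ValueError("count table must start with 'feature' and 'length' columns")

    class _NamedLength:
        __slots__ = ("name", "length")

        def __init__(self, name, length):
            self.name, self.length = name, int(length)

        def __len__(self):
            return self.length

    features = [_NamedLength(n, l) for n, l in zip(df["feature"], df["length"])]
    return CountTable(
        features=features,
        counts=df.iloc[:, 2:].to_numpy(dtype=int),
        sample_names=list(df.columns[2:]),
        lengths=df["length"].to_numpy(),
    )
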
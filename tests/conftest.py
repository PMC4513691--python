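"""Shared fixtures: one synthetic data set per session plus brute-force oracles."""

from collections import Counter

import pytest

from ngstk.fixtures import FixtureSpec, write_fixture_set


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Standard synthetic data set (seed 1) generated once per session."""
    out = tmp_path_factory.mktemp("fixture_set")
    return write_fixture_set(FixtureSpec(seed=1), out)


@pytest.fixture(scope="session")
def sam_path(fixture_set):
    return fixture_set["paths"]["sam"]


def pileup_oracle(intervals):
    """Brute-force per-base coverage: count every base, then run-length merge."""
    per_base = {}
    for chrom, start, end in intervals:
        counts = per_base.setdefault(chrom, Counter())
        for pos in range(start, end):
            counts[pos] += 1
    lines = []
    for chrom in sorted(per_base):
        counts = per_base[chrom]
        run_start = run_val = None
        prev = None
        for pos in sorted(counts):
            val = counts[pos]
            if run_start is not None and (pos != prev + 1 or val != run_val):
                lines.append((chrom, run_start, prev + 1, run_val))
                run_start = None
            if run_start is None:
                run_start, run_val = pos, val
            prev = pos
        if run_start is not None:
            lines.append((chrom, run_start, prev + 1, run_val))
    return lines


def write_sam(path, records, chroms=(("chr1", 10000),)):
    """Write a minimal SAM file from pre-formatted alignment lines."""
    header = ["@HD\tVN:1.6\tSO:unknown"] + [f"@SQ\tSN:{c}\tLN:{n}" for c, n in chroms]
    path.write_text("\n".join(header + list(records)) + "\n")
    return path


def sam_record(qname="r1", flag=0, chrom="chr1", pos0=100, mapq=60, cigar="50M",
               seq=None, qual=None, tags=("NM:i:0", "NH:i:1"), rnext="*", pnext0=-1):
    length = sum(
        int(n) for n, op in _cigar_tokens(cigar) if op in "MIS=X"
    )
    seq = seq or "A" * length
    qual = qual or "I" * length
    return "\t".join(
        [qname, str(flag), chrom, str(pos0 + 1), str(mapq), cigar, rnext,
         str(pnext0 + 1), "0", seq, qual] + list(tags)
    )


def _cigar_tokens(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""
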
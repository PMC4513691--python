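# Methods

This note records the conventions, models and design decisions behind
`ngstk`, in the order a pipeline would meet them.

## Coordinate conventions

All in-memory coordinates are 0-based half-open intervals (the BED
convention): a feature `[start, end)` of length `end − start`. GFF3/GTF use
1-based closed coordinates; the shift (`start − 1`, `end` unchanged) happens
exactly once, at the I/O boundary in `formats`. This single-convention rule
removes the class of off-by-one bugs that arises when both conventions
circulate inside one code base. A 1 bp GFF3 feature `500..500` therefore
becomes BED `499/500`.

Strand is one of `+`, `−`, `.`. Where an operation needs sidedness
(`extend_interval`), `.` deterministically behaves as `+`; this matches
common tool behaviour and is documented rather than guessed per call.

## The interval hierarchy

`GenomicInterval` (chrom/start/end/strand) → `ScoredFeature` (adds BED6 name
and score) → `FeatureChain` (an ordered run of features sharing chrom and
strand, e.g. one transcript's exons) → `FeatureLine` (role label → chains,
e.g. `exon`/`intron`/`SJ` chains of one transcript). Chains forbid
overlapping members: with transcript-exon semantics an overlap is a data
error, and silently merging would corrupt downstream BED12 block structure,
so construction raises naming the offending pair. Role labels are free-form
strings; constraining them to a fixed vocabulary would buy nothing and cost
extensibility. Aggregation above the transcript level (isoform groups,
paralog clusters) is out of scope.

BED12 conversion is exact block arithmetic: `blockStarts[i] = exonStart −
chromStart`, and every emitted record satisfies the full BED12 invariant set
(block count/size/start consistency, last block ending at `chromEnd`, thick
range inside the span). BED scores outside `[0, 1000]` are passed through
with a warning — the nominal cap is widely violated in real files and
truncating silently would lose information.

## Alignment statistics and filtering

SAM/BAM access goes through pysam. Read-level counts use primary alignments
only; `total_alignments` counts every mapped record including secondary and
supplementary ones, so `total_alignments ≥ aligned_reads` always holds. Each
mate of a pair counts as one aligned read.

* **Uniqueness**: NH tag when present (`NH == 1` ⇒ unique). Files without NH
  fall back to a name-collated pass counting reported alignments per
  (read name, mate) key. The NH route is primary because split-read mappers
  in this toolkit's intended workflows emit it.
* **"Missing a mate"**: paired-flag reads whose mate-unmapped flag is set,
  plus reads whose mate record never appears in the file.
* **Clip/match fractions**: soft+hard clipped bases, respectively M/=/X
  bases, divided by the full read length inferred from the CIGAR (hard clips
  included), so both fractions live in [0, 1] per alignment.
* **Alignment quality** is taken as the mean Phred base quality of the
  alignment; MAPQ is additionally histogrammed separately. Both are cheap
  and unambiguous where a vaguer "alignment quality score" would not be.
* **Paired-end strand convention**: fragment strand = strand of read 1 (FR
  library layout); read 2 follows its mate. `library_type="rf"` flips the
  rule. This is the default convention of common stranded protocols and is
  explicit rather than implicit.
* **Coverage**: reference bases under M/=/X and D operations count as
  covered; N splice gaps, insertions and clips do not — standard pileup
  semantics. Coverage is computed by a boundary-event sweep
  (O(n log n)), then run-length merged; tests compare it against a literal
  per-base counting oracle.

## Expression normalization

`count_reads` increments a feature when a primary alignment overlaps it by
at least one aligned (M/=/X) base; half-open abutment is not overlap. A read
overlapping several features increments each — no fractional assignment,
which is a documented limitation, not an accident. For BED12 features only
exonic blocks count.

RPKM and TPM use the standard definitions (formulas in the README). The
library size for RPKM defaults to the column sum of counts over the provided
feature set: this keeps a count table self-contained and reproducible, at
the price of differing from the classical all-mapped-reads denominator when
the annotation does not cover the whole library. An explicit
`library_sizes` / `--total-mapped-reads` override restores the classical
definition. A zero library size yields an all-zero column with a warning
rather than NaNs, so downstream tabulation never propagates missingness.

## Splice junctions

A junction is the pair (donor_end, acceptor_start) bounding an intron
`[donor_end, acceptor_start)`. Mapper output dialects differ only in how the
BED6 name field encodes read support, so the parser is pluggable: the
segemehl grammar (`splits:<reads>:...`) is built in, and the generic
fallback takes the score column, which guarantees operability for any
mapper. Identical junctions are merged with summed support before the
`min_support` threshold applies, so dedup conserves total support.

Known/novel classification is exact coordinate matching against introns
derived from BED12 block gaps (annotation as the user loaded it, not GFF
intron features); `tolerance=N` relaxes to ±N nt per boundary for noisy
data, default 0. Donor/acceptor motifs are the first and last two intronic
nucleotides, reverse-complemented and swapped on the minus strand; canonical
means GT..AG after that correction. Junctions reaching outside the sequence
are flagged and reported as `NN` rather than raising.

The two-block BED12 visualization encoding places `anchor`-nt blocks on the
exonic flanks; a left anchor reaching past position 0 is clamped and the
first block shrunk, which keeps the record valid at chromosome starts.

## UCSC hubs

Hub construction writes the minimal required stanza keys of the public hub
grammar (hub/shortLabel/longLabel/genomesFile/email; genome/trackDb;
track/bigDataUrl/shortLabel/longLabel/type/color/visibility), with fixed key
order and no timestamps so identical configs rebuild byte-identically —
reproducibility by regeneration. Assembly hubs add
twoBitPath/organism/defaultPos/scientificName/description and a default
groups.txt; `defaultPos` defaults to the first chromosome's first kilobase.
Binary encoders are treated as optional externals: BigWig is written via
pyBigWig when available; the genome ships as FASTA with a manifest note in
place of a 2bit file. The validator checks the same grammar the builders
emit plus referenced-file existence, giving a self-validation closure that
tests exercise in both directions (built hubs validate; a removed key yields
exactly one named violation).

## Synthetic fixtures

The generator exists so every component can be tested by exact parameter
recovery rather than by eyeballing plausible output. One integer seed drives
a single pseudo-random stream; identical spec + seed reproduces
byte-identical files, which is also the reproducibility mechanism (no stored
fixtures).

Defaults — 2 chromosomes × 10 kb of uniform ACGT, 20 non-overlapping genes
(30% spliced with 3 exons of 60–120 nt and introns of 60–120 nt), 500 reads
of 50 nt, 40% paired (FR layout), 5% of paired reads missing their mate, 10%
of single-end reads multi-mapped (NH of 2–3 with that many records), 20% of
single-end reads from spliced genes spanning an intron with an N-gap CIGAR,
0–2 mismatches per read recorded in NM — were chosen once as a small but
category-complete RNA-seq-like setting in which every statistic has
double-digit support. Intron termini are forced to GT..AG (genomic CT..AC on
the minus strand) so motif calls have positive controls. The ground-truth
table records the categories actually emitted, so recovery tests assert
exact equality, not approximation.

What the generator deliberately does **not** emulate: realistic base
composition or quality-score distributions, sequencing-error models,
coverage biases, overlapping genes, alternative isoforms, or reads partially
outside genes. Passing recovery tests therefore demonstrates correctness of
the counting/parsing/arithmetic logic under clean conditions, not robustness
to messy real-world libraries.

## Numerical and degenerate-input choices

* TPM columns are validated to sum to 10⁶ within 1e-6 relative error;
  the computation itself is a single normalization, so the tolerance only
  absorbs float summation order.
* Empty inputs are legal wherever a pipeline can produce them: header-only
  SAM gives zero counts and empty histograms; an empty BED gives an empty
  list; zero-track hubs are valid; zero-motif MEME reports give empty
  summaries.
* Parse errors carry file and line number; invariant violations name the
  violated rule and the offending values.
* Ties/ordering: BedGraph lines sort by (chrom, start) with chroms in
  lexicographic order; summary CSV columns have a fixed documented order;
  hub files have fixed key order.

## Known limitations

Gene-level isoform aggregation, GFF3 Parent-graph resolution, GTF writing,
CRAM, duplicate marking, insert-size models, differential expression and
differential splicing are out of scope. BigBed/2bit encoding requires
external tools not bundled here. The segemehl name grammar is implemented
from its documented `splits:<reads>` convention; other mappers should use
the generic score-column dialect or register a parser.
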
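# Methods

## Contiguity statistics

N(X)/L(X) use the standard convention: sort lengths descending, scan the
running cumulative sum, and report the length and count at the first prefix
reaching `X/100 × reference`. Ties between equal lengths are irrelevant to
the result (equal elements are interchangeable under a stable sort). The
curve routine walks all 100 thresholds in a single pass over the sorted
list, but is tested pointwise against an independent brute-force prefix
scan, so the optimisation carries no correctness burden.

NG(X) uses an externally supplied genome-size estimate as the reference.
When the assembly total is below `X/100 × G` the statistic has no defined
value; we report it as undefined (`NA` in CSV, `None` in Python) rather
than 0, because a 0 would corrupt the log-scaled contiguity plots this data
feeds. Once undefined at some threshold, it is undefined at every larger
threshold, and the exporters preserve that truncation instead of padding.

The CLI accepts the genome size in Mb (the unit users think in) and
converts to bp (×10⁶) internally; the library API is bp throughout.

## Scaffold → contig decomposition

A contig is a maximal run not interrupted by `min_gap` or more consecutive
`N`/`n`; the default `min_gap = 10` follows the NCBI assembled-gap
convention. Shorter N runs are treated as ambiguous bases inside a contig,
not as structure. Consequences worth knowing: contig-basis `%N` counts only
the short runs that survived inside contigs, and
`total_contig_bases + splitting-gap bases = total_bases` holds exactly.

## Composition

Counting is case-insensitive (soft-masking is annotation, not composition;
case is preserved for re-output). `GC%` is `(G+C)/(A+C+G+T)` so that gap
content cannot deflate it; `%N` is over total length, as a whole-assembly
figure. IUPAC ambiguity codes other than N are tallied as `other` and
excluded from the GC denominator. Characters outside the IUPAC alphabet are
an error with a position, not silently skipped.

## Annotation model

Coordinates are 1-based inclusive (the GFF convention); all lengths are
`end − start + 1`, and the single statement of the slice conversion —
`[start, end]` ↦ `seq[start−1:end]` — lives in the extraction module.
Feature-type filters default to `gene` / `{mRNA, transcript}` and are
configurable because real annotations disagree about types (ncRNA gene
models, for instance). The hierarchy is resolved in two passes so children
may precede parents; GFF3 multi-valued `Parent` attaches an exon to each
listed transcript, and such an exon counts once per transcript in the exon
totals. Three tolerances are applied rather than hard failures, each with a
warning: exonless transcripts get their declared span as a single exon
(dropping them would silently change counts), overlapping exons within one
transcript are merged, and embedded `##FASTA` sections are skipped.
Unknown attributes are not preserved; round-tripping guarantees
identifiers, coordinates and strands only.

"Mean exons per gene model" is ambiguous in common usage, so the table
reports both readings under separate names: per transcript, and per gene
via its longest (most exons) transcript.

## Transcript extraction

Plus-strand transcripts concatenate exon substrings in ascending start
order; minus-strand transcripts reverse-complement that concatenation.
Output is uppercased: downstream ortholog searches are case-insensitive,
and normalising removes soft-masking noise from the file. Extraction
refuses to run when the annotation↔assembly consistency report is
non-empty (missing seqids or out-of-bounds features, named explicitly) or
when a transcript is unstranded — a silent best-effort would produce
wrong sequences. When the user supplies a transcript FASTA, it takes
precedence over extraction.

## Contamination screening

Two backends share one hit type. The built-in backend finds maximal exact
matches by 16-mer seeding and bidirectional ungapped extension on both
strands, case-insensitively; 16 is small enough to seed any 50 bp match
and large enough that random 16-mer collisions in test-sized data are
negligible. The default reporting floor of 50 bp keeps reported exact
matches comfortably inside the significance regime that the external
backend's `evalue = 1e-25` cutoff implies for a UniVec-scale database.
Both backends keep at most one hit per query (the highest-scoring), which
is what `max_target_seqs = 1, max_hsps = 1` does externally. The external
backend runs NCBI blastn as megablast with exactly those parameters plus
`evalue 1e-25`, via `-subject` so a single executable suffices, and parses
the 12-column tabular output; a missing executable is a hard
"backend unavailable" error, never a silent fallback to the exact backend.
Per-query summaries report the length of the union of hit intervals, so
overlapping hits are not double-counted.

Out of scope by design: adapter trimming, removal of contaminated spans,
and taxonomic labelling of hits.

## Reporting and saved metrics

Saved-metrics files are versioned plain-text `key=value` sections
(`[assembly]`, `[ngx]`, `[annotation]`), chosen over a binary or schema-heavy
format so reference metric sets can be inspected and diffed; `load(save(x))`
is field-for-field lossless, with floats serialized at full precision.
Comparison tables round floats to 2 decimals for display; the objects and
saved files keep full precision. The registry imposes no cap on the number
of entries being compared. In the NG(X) long-format export the threshold-50
row carries a boolean `ng50_marker` column (the conventionally highlighted
NG50 position) rather than an extra marker row, keeping the contract of
exactly one row per defined (label, threshold) pair.

## Synthetic data generator

The generator emulates exactly what the metrics consume: a scaffold length
distribution, N-gap runs at prescribed positions, a target GC reached by
per-base categorical draws (realised GC is within ~1 point of target for
sequences ≥ 10 kb), uniform gene models placed outside gap runs, and vector
inserts overwriting assembly bases at known coordinates on either strand.
Ground truth is derived arithmetically from the prescription — never by
running the measurement code — so generated data is a genuine oracle for
end-to-end recovery tests. Decoy vectors are redrawn until they share no
16-mer with the assembly (checked by brute force), making "zero hits on a
disjoint vector set" a provable expectation rather than a probabilistic one.

What the generator does not emulate: repeat structure, heterozygosity,
sequencing error, realistic gene density or length distributions. Passing
tests therefore demonstrate that the arithmetic and file handling are
correct, not that any biological interpretation of a real genome's metrics
is warranted.

Default study conditions: six scaffolds of 80/70/50/40/30/20 kb (a
hand-checkable length mix whose N50 = 70 kb and, against a 400 kb genome
size, NG50 = 50 kb), GC 46% (typical of plant genomes), 300 bp vectors,
three-exon 150 bp-exon gene models. Test and acceptance runs use these
desk-scale sizes; every routine is linear or n·log n in assembly size, and
the metrics themselves are scale-free.

## Numerical and degenerate-input choices

Medians use the midpoint average for even counts. Thresholds are validated
to 1…100. Empty inputs (FASTA files, record collections, gene lists,
vector databases) are errors, not empty outputs, except where the contract
says otherwise (an all-N sequence yields zero contigs; an empty query set
yields an empty hit list). Duplicate FASTA identifiers and duplicate
registry labels are rejected. gzip is detected from magic bytes, so
miscalled file extensions cannot misroute parsing.
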
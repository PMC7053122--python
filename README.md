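# asmqc

Quality assessment for genome assemblies and gene structure annotations:
contiguity metrics (N50/L50, NG(X)/LG(X) curves), annotation statistics,
spliced transcript extraction, vector-contamination screening, and
side-by-side benchmarking of multiple assemblies.

## Who it is for

Anyone who has just assembled a genome — or is choosing between assemblies —
and wants the standard reference-free quality summary without stitching
together half a dozen one-metric scripts: how contiguous is it, how much of
it is gap, do the gene models look sane, is there cloning-vector
contamination, and how does it all compare to another assembly or to a
reference.

## The statistics

For an assembly of sequences with lengths `l₁ ≥ l₂ ≥ … ≥ lₖ` and total
`T = Σ lᵢ`:

* **N(X)** is `l_j` for the smallest `j` with `l₁ + … + l_j ≥ (X/100)·T`,
  and **L(X)** is that `j`. N50/L50 are the conventional X = 50 values.
* **NG(X)/LG(X)** replace `T` with an externally estimated genome size `G`,
  so assemblies of different completeness become comparable. When the
  assembly is smaller than `(X/100)·G` the value is undefined (reported as
  `NA`, never 0, so log-scaled contiguity plots stay honest). The full
  curve is evaluated at every integer threshold X = 1…100.
* **Scaffold vs contig basis**: scaffolds are split into contigs at runs of
  ≥ 10 consecutive `N` (configurable); every metric is computed on both
  bases. `GC%` is taken over unambiguous bases only; `%N` over total length.
* **Annotation metrics**: gene/transcript/exon counts, exons per transcript
  (and per gene via its longest transcript), genomic gene length, spliced
  transcript length (Σ exon lengths), exon length, mono-exonic transcript
  count.
* **Contamination**: assembly sequences are screened against a UniVec-style
  vector FASTA, either with the built-in exact-match backend (16-mer seeds,
  ungapped maximal extension, both strands, one best hit per query) or with
  NCBI blastn run as `-task megablast -max_target_seqs 1 -max_hsps 1
  -evalue 1e-25`, the standard parameterisation for vector screening.

## Worked example

```python
from asmqc import assembly_metrics, ng_curve
from asmqc.fixtures import FixtureSpec, generate_assembly

spec = FixtureSpec(seed=1,
                   lengths=[80_000, 70_000, 50_000, 40_000, 30_000, 20_000],
                   gap_runs={0: [(10_000, 25)]})
records, _ = generate_assembly(spec, estimated_genome_size=400_000)
scaffold, contig = assembly_metrics(records, estimated_genome_size=400_000)
print(scaffold.n50, scaffold.l50, scaffold.ng50, scaffold.lg50)
```

prints `70000 2 50000 3`: half of the 290 kb assembly is covered by the two
longest scaffolds (so N50 = 70 kb), but half of the *estimated genome*
(200 kb) needs the three longest (so NG50 = 50 kb) — the gap between the
two numbers is the assembly's incompleteness showing. The 25 bp N run
splits one scaffold, so the same call reports 7 contigs from 6 scaffolds
with `contig.n50 = 50000`. Each script in `examples/` is a runnable
narrative like this one (contiguity, annotation statistics, transcript
extraction, contamination screening, benchmarking).

## Command line

```bash
asmqc assembly genome.fa.gz -g 400 -l myasm -o out/   # metrics + NG(X) CSVs (G in Mb)
asmqc annotation genes.gff3 --assembly genome.fa      # annotation metrics table
asmqc extract genome.fa genes.gff3 -o transcripts.fa  # BUSCO-ready transcript FASTA
asmqc screen genome.fa univec.fa -o hits.csv          # contamination hits + summary
asmqc compare out/myasm.metrics.txt ref.metrics.txt   # benchmark saved metric sets
```

`asmqc extract` uses a user-supplied `--transcripts` FASTA when given,
extracting from the assembly only otherwise, and refuses extraction (with a
report naming the offending sequence IDs) when the annotation references
sequences the assembly lacks.

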
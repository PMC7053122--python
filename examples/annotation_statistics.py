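"""Gene-model statistics from a GFF3 annotation.

Generates a small assembly with 12 four-exon genes, writes the annotation to
GFF3, re-parses it, and reports the count and length statistics.
"""

import tempfile
from pathlib import Path

from asmqc import annotation_metrics, parse_annotation
from asmqc.annotation_model import write_gff3
from asmqc.fixtures import FixtureSpec, generate_annotation, generate_assembly

spec = FixtureSpec(seed=2, lengths=[60_000, 40_000], n_genes=12, exons_per_transcript=4)
records, _ = generate_assembly(spec)
genes, truth = generate_annotation(spec, records, label="demo")

with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "demo.gff3"
    write_gff3(genes, gff)
    metrics = annotation_metrics(parse_annotation(gff), label="demo")

print(f"gene models: {metrics.n_genes}  transcripts: {metrics.n_transcripts}")
print(f"exon records: {metrics.n_exons}  exons/transcript: {metrics.mean_exons_per_transcript}")
print(f"mean gene length (genomic span): {metrics.mean_gene_length:.1f} bp")
print(f"mean spliced transcript length: {metrics.mean_transcript_spliced_length:.1f} bp")
print(f"mean exon length: {metrics.mean_exon_length:.1f} bp")
print(f"matches the generator's prescription exactly: {metrics == truth}")

# Gene length counts introns (genomic span); spliced length sums exons only,
# so 4 exons x 150 bp give 600 bp spliced inside a 900 bp gene span.
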
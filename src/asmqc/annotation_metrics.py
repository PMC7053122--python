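"""Count and length statistics of a gene structure annotation.

The statistics mirror the standard annotation quality summary: numbers of
gene models, transcripts and exons, exons per transcript (and per gene via
the gene's longest transcript, since "exons per gene model" is ambiguous in
common usage — both are reported, labeled), and the mean lengths of genes
(genomic span, introns included), spliced transcripts, and exons.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

from .annotation_model import GeneModel


@dataclass
class AnnotationMetrics:
    label: str
    n_genes: int
    n_transcripts: int
    n_exons: int  # exon records summed over transcripts (shared exons count per transcript)
    mean_transcripts_per_gene: float
    mean_exons_per_transcript: float
    mean_exons_per_gene_longest_tx: float
    mean_gene_length: float
    median_gene_length: float
    mean_transcript_spliced_length: float
    mean_exon_length: float
    longest_gene: int
    shortest_gene: int
    n_monoexonic_transcripts: int


def annotation_metrics(genes: Sequence[GeneModel], label: str = "annotation") -> AnnotationMetrics:
    """Compute :class:`AnnotationMetrics` from parsed gene models.

    Gene length is the genomic span ``end - start + 1``; transcript spliced
    length is the sum of its exon lengths; all means are arithmetic and the
    median uses the midpoint average for even counts.
    """
    if not genes:
        raise ValueError("empty gene collection")
    gene_lengths = [g.length for g in genes]
    transcripts = [tx for g in genes for tx in g.transcripts]
    if not transcripts:
        raise ValueError("no transcripts in the annotation")
    exon_counts = [len(tx.exons) for tx in transcripts]
    n_exons = sum(exon_counts)
    spliced = [tx.spliced_length for tx in transcripts]
    exon_lengths = [e.length for tx in transcripts for e in tx.exons]
    longest_tx_exons = [max(len(tx.exons) for tx in g.transcripts) for g in genes]
    return AnnotationMetrics(
        label=label,
        n_genes=len(genes),
        n_transcripts=len(transcripts),
        n_exons=n_exons,
        mean_transcripts_per_gene=len(transcripts) / len(genes),
        mean_exons_per_transcript=n_exons / len(transcripts),
        mean_exons_per_gene_longest_tx=sum(longest_tx_exons) / len(genes),
        mean_gene_length=sum(gene_lengths) / len(genes),
        median_gene_length=float(statistics.median(gene_lengths)),
        mean_transcript_spliced_length=sum(spliced) / len(transcripts),
        mean_exon_length=sum(exon_lengths) / len(exon_lengths),
        longest_gene=max(gene_lengths),
        shortest_gene=min(gene_lengths),
        n_monoexonic_transcripts=sum(1 for c in exon_counts if c == 1),
    )
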
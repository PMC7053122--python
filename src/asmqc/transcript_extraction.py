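"""Spliced transcript sequence extraction from an assembly plus annotation.

This is the gffread-equivalent stage: for each transcript, exon substrings
are concatenated in ascending genomic order and, for minus-strand
transcripts, reverse-complemented. The resulting FASTA is the input that
transcriptome-mode completeness tools (e.g. BUSCO) expect; writing that file
is in scope here, running such tools is not.

Coordinate convention: a GFF 1-based inclusive interval [start, end] maps to
the Python slice ``seq[start-1:end]``. Extracted sequences are uppercased so
downstream case-insensitive ortholog searches see no soft-masking noise.
"""

from __future__ import annotations

from typing import Sequence

from .annotation_model import GeneModel, validate_against_assembly
from .errors import AnnotationError, FastaError
from .sequence_io import IUPAC_NUCLEOTIDES, SequenceRecord

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (N→N, R↔Y, etc.).

    Case is preserved. An involution: applying twice returns the input.
    Raises :class:`FastaError` (with the position) on invalid characters.
    """
    for i, c in enumerate(seq):
        if c.upper() not in IUPAC_NUCLEOTIDES:
            raise FastaError(f"invalid character {c!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_transcripts(
    genes: Sequence[GeneModel], records: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """Extract one spliced, uppercased sequence record per transcript.

    Output order follows annotation order; record ids are transcript ids and
    lengths equal each transcript's spliced length. Refuses to run (raising
    :class:`AnnotationError` carrying the validation report) when the
    annotation is inconsistent with the assembly, and rejects unstranded
    (strand ``.``) transcripts.
    """
    report = validate_against_assembly(genes, records)
    if not report.ok:
        raise AnnotationError(f"annotation inconsistent with assembly:\n{report}")
    seqs = {r.id: r.seq for r in records}
    out: list[SequenceRecord] = []
    for g in genes:
        for tx in g.transcripts:
            if tx.strand not in {"+", "-"}:
                raise AnnotationError(f"unstranded transcript {tx.id!r} (strand {tx.strand!r})")
            genome = seqs[tx.seqid]
            spliced = "".join(genome[e.start - 1 : e.end] for e in tx.exons).upper()
            if tx.strand == "-":
                spliced = reverse_complement(spliced)
            out.append(SequenceRecord(id=tx.id, seq=spliced, description=f"gene={g.id}"))
    return out
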
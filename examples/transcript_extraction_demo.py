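"""Spliced transcript extraction, shown on a hand-checkable 12 bp genome.

chr1 = AAACCCGGGTTT. A transcript with exons at 1-3 and 7-9 splices to
AAAGGG on the plus strand; the same coordinates on the minus strand give
its reverse complement, CCCTTT.
"""

from asmqc import extract_transcripts
from asmqc.annotation_model import ExonInterval, GeneModel, TranscriptModel
from asmqc.sequence_io import SequenceRecord

genome = [SequenceRecord(id="chr1", seq="AAACCCGGGTTT")]


def gene(strand):
    exons = [ExonInterval("chr1", 1, 3, strand), ExonInterval("chr1", 7, 9, strand)]
    tx = TranscriptModel(id="t1", parent_gene="g1", seqid="chr1", strand=strand, exons=exons)
    return GeneModel(id="g1", seqid="chr1", start=1, end=9, strand=strand, transcripts=[tx])


(plus,) = extract_transcripts([gene("+")], genome)
(minus,) = extract_transcripts([gene("-")], genome)
print(f"+ strand: {plus.seq}   (exon bases 1-3 then 7-9)")
print(f"- strand: {minus.seq}   (reverse complement of the + splice)")

# This FASTA-ready output is the input that transcriptome-mode completeness
# tools such as BUSCO expect; a user-supplied transcript file, when present,
# takes precedence over extraction.
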
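import random

import pytest

from asmqc.annotation_model import ExonInterval, GeneModel, TranscriptModel
from asmqc.sequence_io import SequenceRecord


@pytest.fixture
def toy_genome():
    """A 12 bp single-chromosome genome with obvious base blocks."""
    return [SequenceRecord(id="chr1", seq="AAACCCGGGTTT")]


def make_transcript(tid, gid, seqid, strand, exon_coords):
    exons = [ExonInterval(seqid=seqid, start=s, end=e, strand=strand) for s, e in exon_coords]
    return TranscriptModel(id=tid, parent_gene=gid, seqid=seqid, strand=strand, exons=exons)


def make_gene(gid, seqid, strand, exon_coords, tid=None):
    tx = make_transcript(tid or gid.replace("g", "t"), gid, seqid, strand, exon_coords)
    return GeneModel(
        id=gid,
        seqid=seqid,
        start=exon_coords[0][0],
        end=exon_coords[-1][1],
        strand=strand,
        transcripts=[tx],
    )


@pytest.fixture
def two_exon_gene():
    return make_gene("g1", "chr1", "+", [(1, 3), (7, 9)])


def random_records(rng: random.Random, n: int, min_len=20, max_len=500, alphabet="ACGT"):
    recs = []
    for i in range(n):
        length = rng.randint(min_len, max_len)
        recs.append(
            SequenceRecord(
                id=f"seq_{i}",
                seq="".join(rng.choice(alphabet) for _ in range(length)),
                description=f"random record {i}",
            )
        )
    return recs
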
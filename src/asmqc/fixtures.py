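"""Synthetic assemblies, annotations, and vector databases with known truth.

Every generator is a pure function of its seed and spec, and returns the
ground-truth metrics computed *analytically from the spec* (never by running
the modules this package uses to measure real data), so the generated data
can serve as an independent oracle for end-to-end parameter-recovery tests.

What is emulated: scaffold length distributions, assembly gaps (N runs) at
prescribed positions, a target GC content, gene models with prescribed exon
structure placed outside gap runs, and vector inserts planted at known
coordinates on either strand. What is not: repeat structure, sequencing
error, heterozygosity, or realistic gene density — the fixtures exercise
metric arithmetic, not biology.
"""

from __future__ import annotations

import random
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assembly_metrics import AssemblyMetrics, DEFAULT_MIN_GAP
from .annotation_metrics import AnnotationMetrics
from .annotation_model import ExonInterval, GeneModel, TranscriptModel
from .contamination_screen import ContaminationHit
from .sequence_io import SequenceRecord
from .transcript_extraction import reverse_complement


@dataclass
class FixtureSpec:
    """Prescription for one synthetic assembly (+ annotation + vectors).

    ``lengths`` are the scaffold lengths in bp; ``gap_runs[i]`` lists
    ``(position, length)`` N runs inside scaffold i (0-based positions);
    ``gc_target`` is the GC percentage of the random non-gap sequence;
    ``exons_per_transcript``/``exon_length``/``intron_length`` prescribe a
    uniform gene structure; ``planted_vectors`` lists
    ``(vector_id, insert_position, scaffold_id, strand)`` contamination
    inserts (the insert overwrites assembly bases in place).
    """

    seed: int = 0
    lengths: Sequence[int] = (80_000, 70_000, 50_000, 40_000, 30_000, 20_000)
    gap_runs: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    gc_target: float = 46.0  # typical plant-genome GC
    n_genes: int = 20
    exons_per_transcript: int = 3
    exon_length: int = 150
    intron_length: int = 100
    vector_length: int = 300
    planted_vectors: list[tuple[str, int, str, str]] = field(default_factory=list)

    def scaffold_id(self, i: int) -> str:
        return f"scaffold_{i + 1}"


def _random_seq(rng: random.Random, n: int, gc: float) -> str:
    g = gc / 200.0  # per-base probability of each of G and C
    a = (100.0 - gc) / 200.0
    return "".join(rng.choices("ACGT", weights=[a, g, g, a], k=n))


def _nx_bruteforce(lengths: Sequence[int], reference: int, threshold: int):
    """Independent cumulative-sum scan (the analytic truth, not the package code)."""
    acc = 0
    for i, ln in enumerate(sorted(lengths, reverse=True)):
        acc += ln
        if acc >= threshold / 100.0 * reference:
            return ln, i + 1
    return None, None


def _contig_spans_from_spec(length: int, gaps: list[tuple[int, int]], min_gap: int):
    """Contig spans implied by prescribed gap runs (only runs >= min_gap split)."""
    spans = []
    pos = 0
    for gpos, glen in sorted(gaps):
        if glen >= min_gap:
            if gpos > pos:
                spans.append((pos, gpos - pos))
            pos = gpos + glen
    if pos < length:
        spans.append((pos, length - pos))
    return spans


def generate_assembly(
    spec: FixtureSpec,
    estimated_genome_size: Optional[int] = None,
    min_gap: int = DEFAULT_MIN_GAP,
    label: str = "synthetic",
) -> tuple[list[SequenceRecord], AssemblyMetrics]:
    """Generate a synthetic assembly and its analytically derived scaffold truth.

    Deterministic given ``spec.seed``. The truth record carries exact counts
    and length statistics; its ``gc_percent`` is the *target* (the realised
    GC of the random sequence is within ~1 point for scaffolds >= 10 kb).
    """
    rng = random.Random(spec.seed)
    records: list[SequenceRecord] = []
    gap_bases = 0
    n_contigs = 0
    contig_lengths_all: list[int] = []
    for i, length in enumerate(spec.lengths):
        if length < 1:
            raise ValueError(f"scaffold length must be positive, got {length}")
        gaps = sorted(spec.gap_runs.get(i, []))
        for gpos, glen in gaps:
            if gpos < 0 or glen < 1 or gpos + glen > length:
                raise ValueError(
                    f"gap run ({gpos},{glen}) does not fit in scaffold {i} of length {length}"
                )
        seq = list(_random_seq(rng, length, spec.gc_target))
        for gpos, glen in gaps:
            seq[gpos : gpos + glen] = "N" * glen
            gap_bases += glen
        records.append(SequenceRecord(id=spec.scaffold_id(i), seq="".join(seq)))
        spans = _contig_spans_from_spec(length, gaps, min_gap)
        n_contigs += len(spans)
        contig_lengths_all.extend(ln for _, ln in spans)

    lengths = list(spec.lengths)
    total = sum(lengths)
    n50, l50 = _nx_bruteforce(lengths, total, 50)
    n90, l90 = _nx_bruteforce(lengths, total, 90)
    ng50 = lg50 = None
    if estimated_genome_size is not None:
        ng50, lg50 = _nx_bruteforce(lengths, estimated_genome_size, 50)
    splitting_gap_bases = sum(
        glen
        for gaps in spec.gap_runs.values()
        for _, glen in gaps
        if glen >= min_gap
    )
    truth = AssemblyMetrics(
        label=label,
        basis="scaffold",
        n_scaffolds=len(lengths),
        n_contigs=n_contigs,
        total_bases=total,
        total_contig_bases=total - splitting_gap_bases,
        longest_seq=max(lengths),
        shortest_seq=min(lengths),
        mean_length=total / len(lengths),
        median_length=float(statistics.median(lengths)),
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
        gc_percent=spec.gc_target,
        n_percent=100.0 * gap_bases / total,
        ng50=ng50,
        lg50=lg50,
        estimated_genome_size=estimated_genome_size,
    )
    return records, truth


def _gap_blocked(start: int, end: int, gaps: list[tuple[int, int]]) -> bool:
    """True when [start, end) (0-based) intersects any prescribed gap run."""
    return any(start < gpos + glen and gpos < end for gpos, glen in gaps)


def generate_annotation(
    spec: FixtureSpec,
    records: Sequence[SequenceRecord],
    label: str = "synthetic",
) -> tuple[list[GeneModel], AnnotationMetrics]:
    """Place ``spec.n_genes`` uniform gene models on the assembly, with truth.

    Each gene has one transcript of ``exons_per_transcript`` exons of
    ``exon_length`` bp separated by ``intron_length`` bp introns; strands
    alternate. Genes are placed left to right, avoiding prescribed gap runs;
    raises ``ValueError`` when the genome cannot hold the requested count.
    """
    if spec.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    k, el, il = spec.exons_per_transcript, spec.exon_length, spec.intron_length
    gene_len = k * el + (k - 1) * il
    spacing = max(il, 50)
    genes: list[GeneModel] = []
    gi = 0
    for si, rec in enumerate(records):
        gaps = sorted(spec.gap_runs.get(si, []))
        pos = 0  # 0-based placement cursor
        while gi < spec.n_genes and pos + gene_len <= len(rec):
            if _gap_blocked(pos, pos + gene_len, gaps):
                pos += spacing
                continue
            strand = "+" if gi % 2 == 0 else "-"
            gid, tid = f"gene_{gi + 1}", f"tx_{gi + 1}"
            start = pos + 1  # to 1-based
            exons = [
                ExonInterval(
                    seqid=rec.id,
                    start=start + j * (el + il),
                    end=start + j * (el + il) + el - 1,
                    strand=strand,
                )
                for j in range(k)
            ]
            tx = TranscriptModel(id=tid, parent_gene=gid, seqid=rec.id, strand=strand, exons=exons)
            genes.append(
                GeneModel(
                    id=gid,
                    seqid=rec.id,
                    start=start,
                    end=start + gene_len - 1,
                    strand=strand,
                    transcripts=[tx],
                )
            )
            gi += 1
            pos += gene_len + spacing
        if gi == spec.n_genes:
            break
    if gi < spec.n_genes:
        raise ValueError(
            f"genome too small for {spec.n_genes} genes of {gene_len} bp (placed {gi})"
        )
    truth = AnnotationMetrics(
        label=label,
        n_genes=spec.n_genes,
        n_transcripts=spec.n_genes,
        n_exons=spec.n_genes * k,
        mean_transcripts_per_gene=1.0,
        mean_exons_per_transcript=float(k),
        mean_exons_per_gene_longest_tx=float(k),
        mean_gene_length=float(gene_len),
        median_gene_length=float(gene_len),
        mean_transcript_spliced_length=float(k * el),
        mean_exon_length=float(el),
        longest_gene=gene_len,
        shortest_gene=gene_len,
        n_monoexonic_transcripts=spec.n_genes if k == 1 else 0,
    )
    return genes, truth


def generate_vector_db(
    spec: FixtureSpec,
    records: Sequence[SequenceRecord],
    n_decoy_vectors: int = 3,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[ContaminationHit]]:
    """Build a vector database, plant the prescribed inserts, return truth hits.

    Returns ``(vectors, contaminated_records, truth_hits)``. Each entry of
    ``spec.planted_vectors`` overwrites ``vector_length`` assembly bases at
    the given 0-based position with the named vector's sequence (its reverse
    complement for strand '-'). Decoy vectors share no 16-mer with the
    assembly (verified by brute force; the generator redraws until true), so
    an assembly with no planted inserts yields zero hits.
    """
    rng = random.Random(spec.seed + 7_000_003)
    rec_map = {r.id: list(r.seq) for r in records}
    vec_ids = {vid for vid, *_ in spec.planted_vectors}
    vectors: dict[str, str] = {}
    for vid in sorted(vec_ids):
        vectors[vid] = _random_seq(rng, spec.vector_length, 50.0)

    truth: list[ContaminationHit] = []
    for vid, pos, sid, strand in spec.planted_vectors:
        if sid not in rec_map:
            raise ValueError(f"unknown scaffold id {sid!r}")
        seq = rec_map[sid]
        vlen = spec.vector_length
        if pos < 0 or pos + vlen > len(seq):
            raise ValueError(f"insert ({vid}, {pos}) does not fit in {sid}")
        gaps = sorted(
            spec.gap_runs.get(next(i for i in range(len(records)) if records[i].id == sid), [])
        )
        if _gap_blocked(pos, pos + vlen, gaps):
            raise ValueError(f"insert ({vid}, {pos}) collides with a gap run in {sid}")
        insert = vectors[vid] if strand == "+" else reverse_complement(vectors[vid])
        seq[pos : pos + vlen] = insert
        truth.append(
            ContaminationHit(
                query_id=sid,
                subject_id=vid,
                query_start=pos + 1,
                query_end=pos + vlen,
                subject_start=1,
                subject_end=vlen,
                match_length=vlen,
                percent_identity=100.0,
                strand=strand,
            )
        )

    contaminated = [SequenceRecord(id=r.id, seq="".join(rec_map[r.id])) for r in records]

    # Decoy vectors: redraw until they share no 16-mer with the assembly
    # (either strand), so they can never seed a hit.
    assembly_kmers = set()
    for r in contaminated:
        s = r.seq.upper()
        rc = reverse_complement(s)
        for x in (s, rc):
            for i in range(len(x) - 15):
                assembly_kmers.add(x[i : i + 16])
    decoys = []
    for d in range(n_decoy_vectors):
        for _ in range(100):
            cand = _random_seq(rng, spec.vector_length, 50.0)
            if all(cand[i : i + 16] not in assembly_kmers for i in range(len(cand) - 15)):
                decoys.append(SequenceRecord(id=f"decoy_{d + 1}", seq=cand))
                break
        else:
            raise RuntimeError("could not draw a decoy vector disjoint from the assembly")

    vector_records = [SequenceRecord(id=vid, seq=s) for vid, s in vectors.items()] + decoys
    return vector_records, contaminated, truth
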
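"""Parsing of GFF3/GTF gene structure annotations into a validated hierarchy.

The parsed model is gene → transcript → exon with 1-based inclusive
coordinates throughout (the GFF convention); every length is
``end - start + 1``. Line-level column and attribute parsing, including the
GFF3 (``key=value``) versus GTF (``key "value"``) attribute dialects, is
delegated to gffutils; the hierarchy is resolved here in two passes so that
children may precede parents in the file.

Tolerances applied during parsing (each with a warning):

* a transcript with no exon features is given one synthetic exon covering its
  declared span (common in minimal GTFs);
* overlapping exons within one transcript are merged;
* an embedded ``##FASTA`` section is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from gffutils.feature import feature_from_line

from .errors import AnnotationError
from .sequence_io import SequenceRecord, _open_text_auto

DEFAULT_GENE_TYPES = frozenset({"gene"})
DEFAULT_TRANSCRIPT_TYPES = frozenset({"mRNA", "transcript"})


@dataclass(frozen=True)
class ExonInterval:
    seqid: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+", "-" or "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"malformed interval {self.seqid}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    id: str
    parent_gene: str
    seqid: str
    strand: str
    exons: list[ExonInterval] = field(default_factory=list)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


@dataclass
class GeneModel:
    id: str
    seqid: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_gtf_attributes(attr_text: str) -> bool:
    return '"' in attr_text and "=" not in attr_text.split(";", 1)[0]


def _detect_dialect(attr_text: str) -> str:
    """Classify one attribute column as gff3 or gtf by its separator syntax."""
    return "gtf" if _is_gtf_attributes(attr_text) else "gff3"


def parse_annotation(
    path: str | Path,
    dialect: str = "auto",
    gene_types: Sequence[str] | frozenset[str] = DEFAULT_GENE_TYPES,
    transcript_types: Sequence[str] | frozenset[str] = DEFAULT_TRANSCRIPT_TYPES,
) -> list[GeneModel]:
    """Parse a GFF3 or GTF file (plain or gzipped) into gene models.

    ``dialect`` is one of ``gff3``, ``gtf`` or ``auto`` (detected from the
    attribute-column syntax). Features whose type is outside ``gene_types`` /
    ``transcript_types`` / ``{exon}`` are ignored. GFF3 ``Parent`` lists may
    be comma-separated; such an exon is attached to every listed transcript.

    Raises :class:`AnnotationError` on non-integer coordinates, ``end <
    start`` (both with the line number), or exons/transcripts referencing a
    parent that does not exist.
    """
    if dialect not in {"gff3", "gtf", "auto"}:
        raise ValueError(f"dialect must be gff3, gtf or auto, got {dialect!r}")
    gene_types = frozenset(gene_types)
    transcript_types = frozenset(transcript_types)

    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    # Deferred links, resolved after the full file is read (children may
    # precede parents in GFF3).
    transcript_parents: list[tuple[str, str]] = []  # (transcript id, gene id)
    transcript_decl_span: dict[str, tuple[int, int]] = {}
    exon_links: list[tuple[str, ExonInterval]] = []  # (transcript id, exon)

    in_fasta = False
    with _open_text_auto(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("##FASTA"):
                warnings.warn(f"{path}: embedded FASTA section ignored (line {lineno})")
                in_fasta = True
                continue
            if in_fasta or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, found {len(cols)}"
                )
            ftype = cols[2]
            if ftype not in gene_types and ftype not in transcript_types and ftype != "exon":
                continue
            line_dialect = dialect if dialect != "auto" else _detect_dialect(cols[8])
            try:
                feat = feature_from_line(line)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if feat.end < feat.start:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed interval (end {feat.end} < start {feat.start})"
                )
            attrs = feat.attributes

            if line_dialect == "gff3":
                fid = attrs.get("ID", [None])[0]
                parents = [p for v in attrs.get("Parent", []) for p in v.split(",")]
            else:
                fid = None
                parents = []
                gene_id = attrs.get("gene_id", [None])[0]
                tx_id = attrs.get("transcript_id", [None])[0]
                if ftype in gene_types:
                    fid = gene_id
                elif ftype in transcript_types:
                    fid = tx_id
                    parents = [gene_id] if gene_id else []
                else:  # exon
                    parents = [tx_id] if tx_id else []

            if ftype in gene_types:
                if fid is None:
                    raise AnnotationError(f"{path}:{lineno}: gene feature lacks an identifier")
                genes[fid] = GeneModel(
                    id=fid, seqid=feat.seqid, start=feat.start, end=feat.end, strand=feat.strand
                )
            elif ftype in transcript_types:
                if fid is None:
                    raise AnnotationError(
                        f"{path}:{lineno}: transcript feature lacks an identifier"
                    )
                if not parents:
                    raise AnnotationError(
                        f"{path}:{lineno}: transcript {fid!r} has no parent gene"
                    )
                transcripts[fid] = TranscriptModel(
                    id=fid, parent_gene=parents[0], seqid=feat.seqid, strand=feat.strand
                )
                transcript_parents.append((fid, parents[0]))
                transcript_decl_span[fid] = (feat.start, feat.end)
            else:  # exon
                if not parents:
                    raise AnnotationError(f"{path}:{lineno}: exon has no Parent/transcript_id")
                exon = ExonInterval(
                    seqid=feat.seqid, start=feat.start, end=feat.end, strand=feat.strand
                )
                for p in parents:
                    exon_links.append((p, exon))

    # Pass 2: resolve links.
    orphan_transcripts = [tid for tid, gid in transcript_parents if gid not in genes]
    orphan_exons = sorted({tid for tid, _ in exon_links if tid not in transcripts})
    if orphan_transcripts or orphan_exons:
        raise AnnotationError(
            "orphan features: "
            + "; ".join(
                filter(
                    None,
                    [
                        f"transcripts with unknown gene: {sorted(orphan_transcripts)}"
                        if orphan_transcripts
                        else "",
                        f"exons with unknown transcript: {orphan_exons}" if orphan_exons else "",
                    ],
                )
            )
        )
    for tid, exon in exon_links:
        transcripts[tid].exons.append(exon)

    for tid, tx in transcripts.items():
        if not tx.exons:
            start, end = transcript_decl_span[tid]
            warnings.warn(
                f"transcript {tid!r} has no exon features; using its declared span as one exon"
            )
            tx.exons = [ExonInterval(seqid=tx.seqid, start=start, end=end, strand=tx.strand)]
        tx.exons.sort(key=lambda e: (e.start, e.end))
        tx.exons = _merge_overlapping(tid, tx.exons)
        genes[tx.parent_gene].transcripts.append(tx)

    empty = [gid for gid, g in genes.items() if not g.transcripts]
    for gid in empty:
        warnings.warn(f"gene {gid!r} has no transcripts; dropped")
        del genes[gid]
    if not genes:
        raise AnnotationError(f"{path}: no gene models found")
    return list(genes.values())


def _merge_overlapping(tid: str, exons: list[ExonInterval]) -> list[ExonInterval]:
    """Merge overlapping or bookended-overlapping exons of one transcript."""
    merged = [exons[0]]
    warned = False
    for e in exons[1:]:
        last = merged[-1]
        if e.start <= last.end:
            if not warned:
                warnings.warn(f"transcript {tid!r} has overlapping exons; merged")
                warned = True
            merged[-1] = ExonInterval(
                seqid=last.seqid, start=last.start, end=max(last.end, e.end), strand=last.strand
            )
        else:
            merged.append(e)
    return merged


@dataclass
class ValidationReport:
    """Consistency problems between an annotation and an assembly.

    Empty (``ok`` is True) iff every annotated seqid exists in the assembly
    and no feature extends past the end of its sequence.
    """

    missing_seqids: list[str] = field(default_factory=list)
    out_of_bounds: list[str] = field(default_factory=list)  # human-readable entries

    @property
    def ok(self) -> bool:
        return not self.missing_seqids and not self.out_of_bounds

    def __str__(self) -> str:
        if self.ok:
            return "annotation consistent with assembly"
        parts = []
        if self.missing_seqids:
            parts.append(
                "sequence IDs in the annotation absent from the assembly: "
                + ", ".join(self.missing_seqids)
            )
        if self.out_of_bounds:
            parts.append("features beyond sequence ends: " + "; ".join(self.out_of_bounds))
        return "\n".join(parts)


def validate_against_assembly(
    genes: Sequence[GeneModel], records: Sequence[SequenceRecord]
) -> ValidationReport:
    """Check that gene models are placeable on the assembly.

    Reports (a) annotated seqids absent from the assembly and (b) features
    whose end exceeds the length of their sequence. Problems are reported,
    not raised, so the caller decides how to proceed.
    """
    if not genes or not records:
        raise ValueError("both gene models and assembly records are required")
    seq_len = {r.id: len(r) for r in records}
    report = ValidationReport()
    missing: set[str] = set()
    for g in genes:
        if g.seqid not in seq_len:
            missing.add(g.seqid)
            continue
        if g.end > seq_len[g.seqid]:
            report.out_of_bounds.append(
                f"gene {g.id} ends at {g.end} on {g.seqid} (length {seq_len[g.seqid]})"
            )
        for tx in g.transcripts:
            for e in tx.exons:
                if e.end > seq_len.get(e.seqid, 0) and e.seqid in seq_len:
                    report.out_of_bounds.append(
                        f"exon of {tx.id} ends at {e.end} on {e.seqid} "
                        f"(length {seq_len[e.seqid]})"
                    )
    report.missing_seqids = sorted(missing)
    return report


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "asmqc") -> None:
    """Serialize gene models as GFF3 (used for round-trip tests and fixtures)."""
    with open(path, "wt") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            out.write(
                f"{g.seqid}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            for tx in g.transcripts:
                t_start, t_end = tx.span
                out.write(
                    f"{tx.seqid}\t{source}\tmRNA\t{t_start}\t{t_end}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.id};Parent={g.id}\n"
                )
                for e in tx.exons:
                    out.write(
                        f"{e.seqid}\t{source}\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t"
                        f"Parent={tx.id}\n"
                    )
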
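"""Vector-contamination screening against a UniVec-style FASTA database.

Two interchangeable backends produce the same :class:`ContaminationHit`
records:

* :func:`screen_exact` — a built-in exact-substring search (16-mer seeding
  with bidirectional ungapped extension, both strands) that makes the module
  fully testable with no external binaries. Only exact matches are found, so
  every hit has 100% identity and no e-value.
* :func:`screen_external` — a wrapper around NCBI blastn run as megablast
  with ``max_target_seqs=1, max_hsps=1, evalue=1e-25``, the standard
  parameterisation for screening assemblies against the UniVec database.

Both keep at most one hit per query sequence (the highest-scoring one),
mirroring the max_target_seqs/max_hsps setting of the external search.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .errors import BackendUnavailableError, ScreenError
from .sequence_io import SequenceRecord, write_fasta
from .transcript_extraction import reverse_complement

SEED_K = 16
DEFAULT_MIN_MATCH = 50
MEGABLAST_EVALUE = 1e-25


@dataclass(frozen=True)
class ContaminationHit:
    """One match of an assembly sequence to a vector-database entry.

    All coordinates are 1-based inclusive on the forward strand of the
    respective sequence; ``strand`` is '-' when the query matches the
    reverse complement of the vector.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    match_length: int
    percent_identity: float
    strand: str
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.match_length < 1 or self.query_end < self.query_start:
            raise ScreenError(f"malformed hit {self}")
        if not 0 < self.percent_identity <= 100:
            raise ScreenError(f"identity out of range: {self.percent_identity}")


def _seed_index(vectors: Sequence[SequenceRecord], k: int) -> dict[str, list[tuple[int, int]]]:
    """k-mer → [(vector index, 0-based offset), ...] over uppercased vectors."""
    index: dict[str, list[tuple[int, int]]] = {}
    for vi, vec in enumerate(vectors):
        s = vec.seq.upper()
        for off in range(len(s) - k + 1):
            index.setdefault(s[off : off + k], []).append((vi, off))
    return index


def _extend(q: str, v: str, q_off: int, v_off: int, k: int) -> tuple[int, int, int]:
    """Maximal ungapped exact extension of a seed; returns (q_start, v_start, length)."""
    left = 0
    while q_off - left - 1 >= 0 and v_off - left - 1 >= 0 and q[q_off - left - 1] == v[v_off - left - 1]:
        left += 1
    right = 0
    while (
        q_off + k + right < len(q)
        and v_off + k + right < len(v)
        and q[q_off + k + right] == v[v_off + k + right]
    ):
        right += 1
    return q_off - left, v_off - left, k + left + right


def screen_exact(
    records: Sequence[SequenceRecord],
    vectors: Sequence[SequenceRecord],
    min_match: int = DEFAULT_MIN_MATCH,
) -> list[ContaminationHit]:
    """Find maximal exact matches of length >= ``min_match`` on both strands.

    Matching is case-insensitive. At most one hit per query is retained
    (the longest; ties broken by query coordinate). ``min_match`` must be at
    least the seed length (16). Raises :class:`ScreenError` on an empty
    vector database.
    """
    if not vectors:
        raise ScreenError("empty vector database")
    if min_match < SEED_K:
        raise ScreenError(f"min_match must be >= {SEED_K}, got {min_match}")
    index = _seed_index(vectors, SEED_K)
    hits: list[ContaminationHit] = []
    for rec in records:
        best: Optional[ContaminationHit] = None
        for strand in "+-":
            q = rec.seq.upper() if strand == "+" else reverse_complement(rec.seq.upper())
            seen: set[tuple[int, int, int, int]] = set()
            for q_off in range(len(q) - SEED_K + 1):
                kmer = q[q_off : q_off + SEED_K]
                for vi, v_off in index.get(kmer, ()):
                    v = vectors[vi].seq.upper()
                    qs, vs, length = _extend(q, v, q_off, v_off, SEED_K)
                    key = (vi, qs, vs, length)
                    if key in seen or length < min_match:
                        seen.add(key)
                        continue
                    seen.add(key)
                    if strand == "+":
                        q_start, q_end = qs + 1, qs + length
                    else:
                        # Map coordinates on the reverse complement back to
                        # the forward strand of the query.
                        q_start = len(q) - (qs + length) + 1
                        q_end = len(q) - qs
                    hit = ContaminationHit(
                        query_id=rec.id,
                        subject_id=vectors[vi].id,
                        query_start=q_start,
                        query_end=q_end,
                        subject_start=vs + 1,
                        subject_end=vs + length,
                        match_length=length,
                        percent_identity=100.0,
                        strand=strand,
                    )
                    if best is None or (hit.match_length, -hit.query_start) > (
                        best.match_length,
                        -best.query_start,
                    ):
                        best = hit
        if best is not None:
            hits.append(best)
    return hits


def screen_external(
    records: Sequence[SequenceRecord],
    vectors: Sequence[SequenceRecord],
    aligner_path: str | Path = "blastn",
) -> list[ContaminationHit]:
    """Screen with NCBI blastn (megablast) using the standard UniVec settings.

    Invokes ``aligner_path`` with ``-task megablast -max_target_seqs 1
    -max_hsps 1 -evalue 1e-25`` and parses its 12-column tabular output.
    Raises :class:`BackendUnavailableError` when the executable is absent
    (never a silent fallback) and :class:`ScreenError` on a nonzero exit,
    carrying the program's diagnostic output.
    """
    if not vectors:
        raise ScreenError("empty vector database")
    resolved = shutil.which(str(aligner_path))
    if resolved is None:
        raise BackendUnavailableError(f"backend unavailable: {aligner_path!r} not found")
    if not records:
        return []
    with tempfile.TemporaryDirectory(prefix="asmqc_screen_") as tmp:
        qpath = Path(tmp) / "query.fa"
        vpath = Path(tmp) / "vectors.fa"
        write_fasta(records, qpath)
        write_fasta(vectors, vpath)
        cmd = [
            resolved,
            "-task", "megablast",
            "-query", str(qpath),
            "-subject", str(vpath),
            "-max_target_seqs", "1",
            "-max_hsps", "1",
            "-evalue", str(MEGABLAST_EVALUE),
            "-outfmt", "6",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ScreenError(
                f"alignment backend failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        return _parse_tabular(proc.stdout)


def _parse_tabular(text: str) -> list[ContaminationHit]:
    """Parse 12-column blast tabular output (outfmt 6) into hits."""
    hits = []
    for line in text.splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ScreenError(f"unparseable tabular line: {line!r}")
        sstart, send = int(f[8]), int(f[9])
        strand = "+" if send >= sstart else "-"
        hits.append(
            ContaminationHit(
                query_id=f[0],
                subject_id=f[1],
                percent_identity=float(f[2]),
                match_length=int(f[3]),
                query_start=int(f[6]),
                query_end=int(f[7]),
                subject_start=min(sstart, send),
                subject_end=max(sstart, send),
                strand=strand,
                evalue=float(f[10]),
            )
        )
    return hits


def contamination_summary(
    hits: Sequence[ContaminationHit], records: Sequence[SequenceRecord]
) -> dict[str, dict[str, float]]:
    """Per-query summary: hit count, contaminated bp, contaminated fraction.

    Contaminated bp is the length of the union of hit intervals on the
    query, so overlapping hits are not double-counted. Every record gets an
    entry (zeros when clean). Raises :class:`ScreenError` for a hit whose
    query id is not among the records.
    """
    lengths = {r.id: len(r) for r in records}
    intervals: dict[str, list[tuple[int, int]]] = {r.id: [] for r in records}
    counts: dict[str, int] = {r.id: 0 for r in records}
    for h in hits:
        if h.query_id not in lengths:
            raise ScreenError(f"hit references unknown query id {h.query_id!r}")
        intervals[h.query_id].append((h.query_start, h.query_end))
        counts[h.query_id] += 1
    summary: dict[str, dict[str, float]] = {}
    for qid, ivs in intervals.items():
        covered = 0
        ivs.sort()
        cur_start = cur_end = None
        for s, e in ivs:
            if cur_end is None or s > cur_end + 1:
                if cur_end is not None:
                    covered += cur_end - cur_start + 1
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        if cur_end is not None:
            covered += cur_end - cur_start + 1
        summary[qid] = {
            "n_hits": counts[qid],
            "contaminated_bp": covered,
            "fraction": covered / lengths[qid],
        }
    return summary
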
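"""FASTA input/output and nucleotide composition counting.

Files may be plain text or gzip-compressed; compression is detected from the
magic bytes, not the file name. Identifiers follow the convention used by GFF
column 1: the first whitespace-delimited token of the header line. Soft-masked
(lowercase) bases are preserved as read but counted case-insensitively.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaError

# Full IUPAC nucleotide alphabet (unambiguous + ambiguity codes).
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")
_AMBIGUITY_NOT_N = frozenset("RYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder of the header (possibly empty);
    ``seq`` is the nucleotide string with case preserved as read.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaError(f"invalid identifier {self.id!r}: must be non-empty, no whitespace")
        if len(self.seq) == 0:
            raise FastaError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text_auto(path: str | Path) -> io.TextIOBase:
    """Open a file as text, transparently gunzipping when magic bytes present."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8", newline=None)
    return open(path, "rt", encoding="utf-8", newline=None)


def read_fasta(path: str | Path, allow_gzip: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of :class:`SequenceRecord`.

    Sequence lines are concatenated with internal whitespace (including
    Windows line endings) removed. Raises :class:`FastaError` on an empty
    file, a record with no sequence characters, or duplicate identifiers.
    """
    path = Path(path)
    if not allow_gzip:
        with open(path, "rb") as fh:
            if fh.read(2) == b"\x1f\x8b":
                raise FastaError(f"{path}: gzip input not permitted here")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text_auto(path) as handle:
        head = handle.read(1)
        while head and head.isspace():
            head = handle.read(1)
        if not head:
            raise FastaError(f"{path}: empty input")
        if head != ">":
            raise FastaError(f"{path}: not FASTA (first non-blank character is {head!r}, expected '>')")
        handle.seek(0)
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise FastaError(f"{path}: record with empty header")
            rec_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            seq = "".join(seq.split())
            if not seq:
                raise FastaError(f"{path}: empty sequence for record {rec_id!r}")
            if rec_id in seen:
                raise FastaError(f"{path}: duplicate identifier {rec_id!r}")
            seen.add(rec_id)
            records.append(SequenceRecord(id=rec_id, seq=seq, description=description))
    if not records:
        raise FastaError(f"{path}: empty input")
    return records


def write_fasta(
    records: Sequence[SequenceRecord] | Iterable[SequenceRecord],
    path: str | Path,
    line_width: int = 60,
) -> None:
    """Write records as FASTA with sequence lines wrapped at ``line_width``.

    ``read_fasta(write_fasta(x)) == x`` on (id, description, seq).
    """
    records = list(records)
    if not records:
        raise FastaError("refusing to write an empty record collection")
    if line_width < 1:
        raise ValueError(f"line_width must be >= 1, got {line_width}")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.seq), line_width):
                out.write(rec.seq[i : i + line_width] + "\n")


def base_composition(seq: str) -> dict[str, int]:
    """Case-insensitive base counts ``{A, C, G, T, N, other}``.

    ``other`` collects IUPAC ambiguity codes that are not N (R, Y, S, W, K,
    M, B, D, H, V) plus U. Counts sum to ``len(seq)``. Raises
    :class:`FastaError` (with the 0-based position) on any character outside
    the IUPAC nucleotide alphabet.
    """
    if not seq:
        raise FastaError("cannot compute composition of an empty sequence")
    counts = {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0, "other": 0}
    for i, c in enumerate(seq):
        u = c.upper()
        if u in counts:
            counts[u] += 1
        elif u in _AMBIGUITY_NOT_N or u == "U":
            counts["other"] += 1
        else:
            raise FastaError(f"invalid character {c!r} at position {i}")
    return counts
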
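"""Contiguity and composition statistics for genome assemblies.

Implements the standard length metrics (N50/L50, N90/L90 and the genome-size
normalised NG50/LG50), the full N(X)/NG(X) curve over every integer threshold
1–100, and the decomposition of scaffolds into contigs at runs of assembly
gaps (N characters).

Conventions
-----------
* N(X) is the length of the shortest sequence in the smallest set of longest
  sequences whose summed length reaches X% of the assembly total; L(X) is the
  number of sequences in that set. NG(X)/LG(X) replace the assembly total with
  an externally estimated genome size G, and are undefined when the assembly
  is smaller than X% of G.
* A splitting gap is a run of at least ``min_gap`` consecutive N (default 10,
  the NCBI assembled-gap convention); shorter N runs stay inside contigs.
* GC% is computed over unambiguous bases only (A+C+G+T); %N over total length.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

from .sequence_io import SequenceRecord, base_composition

DEFAULT_MIN_GAP = 10


@dataclass
class AssemblyMetrics:
    """Per-assembly statistics on one basis (whole scaffolds or split contigs)."""

    label: str
    basis: str  # "scaffold" or "contig": which lengths the order statistics use
    n_scaffolds: int
    n_contigs: int
    total_bases: int
    total_contig_bases: int
    longest_seq: int
    shortest_seq: int
    mean_length: float
    median_length: float
    n50: int
    l50: int
    n90: int
    l90: int
    gc_percent: float
    n_percent: float
    ng50: Optional[int] = None
    lg50: Optional[int] = None
    estimated_genome_size: Optional[int] = None


@dataclass
class NGCurve:
    """N(X)- or NG(X)-style curve over integer thresholds 1..100.

    ``values[i]``/``l_values[i]`` correspond to ``thresholds[i]``; both are
    ``None`` once the assembly total falls short of threshold% of
    ``reference_size`` (and stay ``None`` for all larger thresholds).
    """

    label: str
    basis: str
    reference_size: int
    thresholds: list[int]
    values: list[Optional[int]]
    l_values: list[Optional[int]]


_GAP_RE_CACHE: dict[int, re.Pattern] = {}


def split_into_contigs(seq: str, min_gap: int = DEFAULT_MIN_GAP) -> list[tuple[int, int]]:
    """Split a scaffold sequence into contig spans at long N runs.

    Returns ``(start, length)`` pairs with 0-based starts, in order. Contigs
    are maximal runs not interrupted by ``min_gap`` or more consecutive N/n;
    shorter N runs remain inside a contig. An all-gap sequence yields ``[]``.
    """
    if not seq:
        raise ValueError("empty sequence")
    if min_gap < 1:
        raise ValueError(f"min_gap must be >= 1, got {min_gap}")
    if min_gap not in _GAP_RE_CACHE:
        _GAP_RE_CACHE[min_gap] = re.compile("[Nn]{%d,}" % min_gap)
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _GAP_RE_CACHE[min_gap].finditer(seq):
        if m.start() > pos:
            spans.append((pos, m.start() - pos))
        pos = m.end()
    if pos < len(seq):
        spans.append((pos, len(seq) - pos))
    return spans


def nx_from_lengths(
    lengths: Sequence[int], reference_size: int, threshold: int
) -> tuple[Optional[int], Optional[int]]:
    """N(X)/L(X) of a length list against a reference size at one threshold.

    Lengths are sorted descending; the N value is the length of the first
    element at which the running cumulative sum reaches
    ``threshold/100 * reference_size``, and the L value is the number of
    elements in that prefix. Returns ``(None, None)`` when the total never
    reaches the target.
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("all lengths must be positive")
    if reference_size <= 0:
        raise ValueError(f"reference_size must be positive, got {reference_size}")
    if not 1 <= threshold <= 100:
        raise ValueError(f"threshold must be in 1..100, got {threshold}")
    target = threshold / 100.0 * reference_size
    cumulative = 0
    for i, length in enumerate(sorted(lengths, reverse=True)):
        cumulative += length
        if cumulative >= target:
            return length, i + 1
    return None, None


def ng_curve(
    lengths: Sequence[int],
    reference_size: int,
    label: str = "",
    basis: str = "scaffold",
) -> NGCurve:
    """Evaluate :func:`nx_from_lengths` at every integer threshold 1..100.

    With ``reference_size`` equal to the assembly total this is the N(X)
    curve; with an estimated genome size it is the NG(X) curve.
    """
    desc = sorted(lengths, reverse=True)
    if not desc:
        raise ValueError("empty length list")
    if any(x <= 0 for x in desc):
        raise ValueError("all lengths must be positive")
    if reference_size <= 0:
        raise ValueError(f"reference_size must be positive, got {reference_size}")
    total = sum(desc)
    thresholds = list(range(1, 101))
    values: list[Optional[int]] = []
    l_values: list[Optional[int]] = []
    # Single pass: for each threshold walk the cumulative sum forward from
    # where the previous (smaller) threshold stopped.
    cumulative = desc[0]
    idx = 0
    for t in thresholds:
        target = t / 100.0 * reference_size
        if total < target:
            values.append(None)
            l_values.append(None)
            continue
        while cumulative < target:
            idx += 1
            cumulative += desc[idx]
        values.append(desc[idx])
        l_values.append(idx + 1)
    return NGCurve(
        label=label,
        basis=basis,
        reference_size=reference_size,
        thresholds=thresholds,
        values=values,
        l_values=l_values,
    )


def _pooled_composition(seqs: list[str]) -> dict[str, int]:
    totals = {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0, "other": 0}
    for s in seqs:
        for k, v in base_composition(s).items():
            totals[k] += v
    return totals


def _order_stats(lengths: list[int]) -> tuple[int, int, float, float]:
    return (
        max(lengths),
        min(lengths),
        sum(lengths) / len(lengths),
        float(statistics.median(lengths)),  # midpoint average for even counts
    )


def _metrics_for_basis(
    label: str,
    basis: str,
    lengths: list[int],
    comp: dict[str, int],
    n_scaffolds: int,
    n_contigs: int,
    total_contig_bases: int,
    estimated_genome_size: Optional[int],
) -> AssemblyMetrics:
    total = sum(lengths)
    longest, shortest, mean_len, median_len = _order_stats(lengths)
    n50, l50 = nx_from_lengths(lengths, total, 50)
    n90, l90 = nx_from_lengths(lengths, total, 90)
    ng50 = lg50 = None
    if estimated_genome_size is not None:
        ng50, lg50 = nx_from_lengths(lengths, estimated_genome_size, 50)
    acgt = comp["A"] + comp["C"] + comp["G"] + comp["T"]
    gc = 100.0 * (comp["G"] + comp["C"]) / acgt if acgt else 0.0
    n_pct = 100.0 * comp["N"] / total if total else 0.0
    return AssemblyMetrics(
        label=label,
        basis=basis,
        n_scaffolds=n_scaffolds,
        n_contigs=n_contigs,
        total_bases=total,
        total_contig_bases=total_contig_bases,
        longest_seq=longest,
        shortest_seq=shortest,
        mean_length=mean_len,
        median_length=median_len,
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
        gc_percent=gc,
        n_percent=n_pct,
        ng50=ng50,
        lg50=lg50,
        estimated_genome_size=estimated_genome_size,
    )


def assembly_metrics(
    records: Sequence[SequenceRecord],
    estimated_genome_size: Optional[int] = None,
    min_gap: int = DEFAULT_MIN_GAP,
    label: str = "assembly",
) -> tuple[AssemblyMetrics, AssemblyMetrics]:
    """Compute scaffold-basis and contig-basis metrics for an assembly.

    Scaffold metrics use whole-record lengths; contig metrics use the spans
    from :func:`split_into_contigs` pooled across records. ``ng50``/``lg50``
    are present only when ``estimated_genome_size`` (bp) is given.
    """
    if not records:
        raise ValueError("empty record collection")
    scaffold_lengths = [len(r) for r in records]
    scaffold_comp = _pooled_composition([r.seq for r in records])

    contig_seqs: list[str] = []
    for r in records:
        for start, length in split_into_contigs(r.seq, min_gap):
            contig_seqs.append(r.seq[start : start + length])
    if not contig_seqs:
        raise ValueError("assembly contains no contig bases (all gaps)")
    contig_lengths = [len(s) for s in contig_seqs]
    contig_comp = _pooled_composition(contig_seqs)
    total_contig_bases = sum(contig_lengths)

    scaffold = _metrics_for_basis(
        label,
        "scaffold",
        scaffold_lengths,
        scaffold_comp,
        len(records),
        len(contig_seqs),
        total_contig_bases,
        estimated_genome_size,
    )
    contig = _metrics_for_basis(
        label,
        "contig",
        contig_lengths,
        contig_comp,
        len(records),
        len(contig_seqs),
        total_contig_bases,
        estimated_genome_size,
    )
    return scaffold, contig
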
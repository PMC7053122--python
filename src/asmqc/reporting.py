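"""Comparison tables, NG(X) plot data, and saved-metrics files.

A :class:`MetricsRegistry` collects per-assembly results — assembly metrics
(scaffold and contig basis), the NG(X) curve, and optionally annotation
metrics — under unique labels, either computed in the current run or loaded
from a saved-metrics file. This is the benchmarking layer: registering a
previously saved "reference" entry alongside a freshly computed assembly
puts them side by side in the same tables and plot data. Any number of
entries may be registered.

Saved-metrics files are a plain-text ``key=value`` format with a version
line, documented by :func:`save_metrics`; ``load_metrics(save_metrics(x))``
is the identity on every field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .assembly_metrics import AssemblyMetrics, NGCurve
from .annotation_metrics import AnnotationMetrics
from .errors import MetricsFileError

FORMAT_VERSION = 1

# Row order of the assembly comparison table.
_ASSEMBLY_ROWS = [
    "n_scaffolds",
    "n_contigs",
    "total_bases",
    "total_contig_bases",
    "longest_seq",
    "shortest_seq",
    "mean_length",
    "median_length",
    "n50",
    "l50",
    "n90",
    "l90",
    "ng50",
    "lg50",
    "gc_percent",
    "n_percent",
    "estimated_genome_size",
]
_ANNOTATION_ROWS = [
    "n_genes",
    "n_transcripts",
    "n_exons",
    "mean_transcripts_per_gene",
    "mean_exons_per_transcript",
    "mean_exons_per_gene_longest_tx",
    "mean_gene_length",
    "median_gene_length",
    "mean_transcript_spliced_length",
    "mean_exon_length",
    "longest_gene",
    "shortest_gene",
    "n_monoexonic_transcripts",
]


@dataclass
class RegistryEntry:
    label: str
    assembly: AssemblyMetrics
    ngx: Optional[NGCurve] = None
    annotation: Optional[AnnotationMetrics] = None
    provenance: str = "computed"  # "computed" or "loaded"


class MetricsRegistry:
    """Ordered collection of labelled metric sets for benchmarking."""

    def __init__(self) -> None:
        self._entries: dict[str, RegistryEntry] = {}

    def add(self, entry: RegistryEntry) -> None:
        if entry.label in self._entries:
            raise MetricsFileError(f"duplicate label {entry.label!r} in registry")
        self._entries[entry.label] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __getitem__(self, label: str) -> RegistryEntry:
        return self._entries[label]

    @property
    def labels(self) -> list[str]:
        return list(self._entries)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    return repr(value) if isinstance(value, float) else str(value)


def _write_section(out, name: str, obj) -> None:
    out.write(f"[{name}]\n")
    for f in dc_fields(obj):
        out.write(f"{f.name}={_fmt(getattr(obj, f.name))}\n")


def save_metrics(entry: RegistryEntry, path: str | Path) -> None:
    """Write a registry entry as a versioned plain-text key=value file.

    Layout: a ``#asmqc-metrics vN`` header, then ``[assembly]``, optional
    ``[ngx]`` (curve points as ``t<threshold>=<value>,<l_value>``), and
    optional ``[annotation]`` sections. Undefined values render as ``NA``.
    """
    with open(path, "wt") as out:
        out.write(f"#asmqc-metrics v{FORMAT_VERSION}\n")
        out.write(f"label={entry.label}\n")
        out.write(f"provenance={entry.provenance}\n")
        _write_section(out, "assembly", entry.assembly)
        if entry.ngx is not None:
            out.write("[ngx]\n")
            out.write(f"label={entry.ngx.label}\n")
            out.write(f"basis={entry.ngx.basis}\n")
            out.write(f"reference_size={entry.ngx.reference_size}\n")
            for t, v, l in zip(entry.ngx.thresholds, entry.ngx.values, entry.ngx.l_values):
                out.write(f"t{t}={_fmt(v)},{_fmt(l)}\n")
        if entry.annotation is not None:
            _write_section(out, "annotation", entry.annotation)


def _parse_scalar(text: str, ftype) -> object:
    if text == "NA":
        return None
    if ftype is int or ftype == "int" or ftype == "Optional[int]":
        return int(text)
    if ftype is float or ftype == "float":
        return float(text)
    return text


def _read_section(lines: list[str], i: int, cls) -> tuple[object, int]:
    values: dict[str, object] = {}
    types = {f.name: f.type for f in dc_fields(cls)}
    while i < len(lines) and not lines[i].startswith("["):
        key, _, raw = lines[i].partition("=")
        if key not in types:
            raise MetricsFileError(f"unknown field {key!r} in [{cls.__name__}] section")
        values[key] = _parse_scalar(raw, types[key])
        i += 1
    missing = [n for n in types if n not in values]
    if missing:
        raise MetricsFileError(f"missing required field(s) in saved metrics: {missing}")
    return cls(**values), i


def load_metrics(path: str | Path) -> RegistryEntry:
    """Read a file written by :func:`save_metrics`; lossless on every field."""
    lines = [ln.rstrip("\n") for ln in open(path, "rt") if ln.strip()]
    if not lines or not lines[0].startswith("#asmqc-metrics v"):
        raise MetricsFileError(f"{path}: not a saved-metrics file")
    version = lines[0].split("v")[-1]
    if version != str(FORMAT_VERSION):
        raise MetricsFileError(f"{path}: unsupported format version {version!r}")
    label = provenance = None
    i = 1
    while i < len(lines) and not lines[i].startswith("["):
        key, _, raw = lines[i].partition("=")
        if key == "label":
            label = raw
        elif key == "provenance":
            provenance = raw
        i += 1
    if label is None:
        raise MetricsFileError(f"{path}: missing required field 'label'")
    assembly = ngx = annotation = None
    while i < len(lines):
        section = lines[i].strip("[]")
        i += 1
        if section == "assembly":
            assembly, i = _read_section(lines, i, AssemblyMetrics)
        elif section == "annotation":
            annotation, i = _read_section(lines, i, AnnotationMetrics)
        elif section == "ngx":
            meta: dict[str, str] = {}
            thresholds: list[int] = []
            values: list[Optional[int]] = []
            l_values: list[Optional[int]] = []
            while i < len(lines) and not lines[i].startswith("["):
                key, _, raw = lines[i].partition("=")
                if key.startswith("t") and key[1:].isdigit():
                    thresholds.append(int(key[1:]))
                    v_raw, _, l_raw = raw.partition(",")
                    values.append(None if v_raw == "NA" else int(v_raw))
                    l_values.append(None if l_raw == "NA" else int(l_raw))
                else:
                    meta[key] = raw
                i += 1
            for req in ("label", "basis", "reference_size"):
                if req not in meta:
                    raise MetricsFileError(f"{path}: missing required field '{req}' in [ngx]")
            ngx = NGCurve(
                label=meta["label"],
                basis=meta["basis"],
                reference_size=int(meta["reference_size"]),
                thresholds=thresholds,
                values=values,
                l_values=l_values,
            )
        else:
            raise MetricsFileError(f"{path}: unknown section [{section}]")
    if assembly is None:
        raise MetricsFileError(f"{path}: missing required [assembly] section")
    return RegistryEntry(
        label=label,
        assembly=assembly,
        ngx=ngx,
        annotation=annotation,
        provenance=provenance or "loaded",
    )


def comparison_table(registry: MetricsRegistry, which: str = "assembly") -> pd.DataFrame:
    """Side-by-side metric table: rows are metric names, columns are labels.

    Columns follow registry insertion order. For ``which="annotation"``,
    entries lacking annotation metrics render as ``"NA"`` down the column.
    """
    if len(registry) == 0:
        raise ValueError("empty registry")
    if which not in {"assembly", "annotation"}:
        raise ValueError(f"which must be 'assembly' or 'annotation', got {which!r}")
    rows = _ASSEMBLY_ROWS if which == "assembly" else _ANNOTATION_ROWS
    data = {}
    for entry in registry:
        obj = entry.assembly if which == "assembly" else entry.annotation
        col = []
        for name in rows:
            if obj is None:
                col.append("NA")
                continue
            v = getattr(obj, name)
            if v is None:
                col.append("NA")
            elif isinstance(v, float):
                col.append(f"{v:.2f}")  # tabular output rounds; JSON/objects keep full precision
            else:
                col.append(str(v))
        data[entry.label] = col
    return pd.DataFrame(data, index=rows)


def ngx_plot_data(registry: MetricsRegistry) -> pd.DataFrame:
    """Long-format NG(X) curve data across all registered assemblies.

    One row per (label, threshold) pair where the curve is defined, with
    columns ``label, threshold, value, l_value, ng50_marker``; the marker
    flags the threshold-50 row of each label (the conventionally reported
    NG50 point, drawn as a vertical line in contiguity plots).
    """
    if len(registry) == 0:
        raise ValueError("empty registry")
    rows = []
    for entry in registry:
        if entry.ngx is None:
            continue
        for t, v, l in zip(entry.ngx.thresholds, entry.ngx.values, entry.ngx.l_values):
            if v is None:
                continue
            rows.append(
                {
                    "label": entry.label,
                    "threshold": t,
                    "value": v,
                    "l_value": l,
                    "ng50_marker": t == 50,
                }
            )
    return pd.DataFrame(rows, columns=["label", "threshold", "value", "l_value", "ng50_marker"])


def plot_ngx(registry: MetricsRegistry, path: str | Path) -> None:
    """Render the NG(X) curves (log-scaled lengths) to an image file.

    Thin optional layer over :func:`ngx_plot_data`; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = ngx_plot_data(registry)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, grp in df.groupby("label", sort=False):
        ax.plot(grp["threshold"], grp["value"], label=label)
    ax.axvline(50, color="black", lw=1.5)
    ax.set_yscale("log")
    ax.set_xlabel("NG(X) threshold (%)")
    ax.set_ylabel("sequence length (bp)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
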
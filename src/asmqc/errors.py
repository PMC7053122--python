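"""Exception hierarchy shared across the package."""


class AsmQCError(Exception):
    """Base class for all asmqc errors."""


class FastaError(AsmQCError):
    """Malformed or unusable FASTA input."""


class AnnotationError(AsmQCError):
    """Malformed or inconsistent GFF3/GTF input."""


class ScreenError(AsmQCError):
    """Contamination-screen configuration or backend failure."""


class BackendUnavailableError(ScreenError):
    """The requested external alignment backend is not present."""


class MetricsFileError(AsmQCError):
    """Unreadable or version-incompatible saved-metrics file."""
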
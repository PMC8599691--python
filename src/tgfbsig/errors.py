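"""Exception hierarchy for the pipeline.

Every error raised on bad user input derives from :class:`PipelineError` so the
CLI can catch one type and exit with a one-line diagnostic.
"""


class PipelineError(Exception):
    """Base class for all pipeline-level failures."""


class FormatError(PipelineError):
    """A file does not conform to its declared format (TSV/GMT parse failures)."""


class ValidationError(PipelineError):
    """Parsed data violates a domain invariant (negative survival time, etc.)."""


class ScaleError(PipelineError):
    """An operation received a matrix on the wrong scale (log2 vs linear)."""


class CoverageError(PipelineError):
    """Too few signature genes are present in the expression matrix."""

    def __init__(self, message: str, missing_genes=()):
        super().__init__(message)
        self.missing_genes = sorted(missing_genes)


class ConfigError(PipelineError):
    """Invalid simulation or pipeline configuration."""


class DegenerateTableError(PipelineError):
    """A contingency table has an empty margin or zero expected count."""


class GroupingError(PipelineError):
    """A group/stratum required by a statistical test is empty."""
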
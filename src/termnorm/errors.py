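"""Exception hierarchy shared across the pipeline stages."""


class TermnormError(Exception):
    """Base class for all package errors."""


class SchemaError(TermnormError):
    """An input file is missing required columns or is otherwise malformed."""


class ValidationError(TermnormError):
    """A row or value violates a data-model invariant."""


class SizingError(TermnormError):
    """Too few eligible rows for the requested sampling design."""


class TemplateError(TermnormError):
    """A prompt template is missing or duplicating a required placeholder."""


class JoinError(TermnormError):
    """A response references an unknown instance, or instances are duplicated."""


class CoverageError(TermnormError):
    """Baseline and fine-tuned responses do not cover the same instances."""


class DegenerateInputError(TermnormError):
    """Input is numerically degenerate for the requested statistic."""
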
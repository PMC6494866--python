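"""Exception hierarchy shared across the package."""


class MicrodysError(Exception):
    """Base class for all package errors."""


class FormatError(MicrodysError):
    """Malformed or contract-violating input file/table."""


class EmptyResultError(MicrodysError):
    """An operation removed every sample/taxon."""


class DegenerateInputError(MicrodysError):
    """Input is valid but statistically degenerate (e.g. zero variance)."""
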
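"""Exception hierarchy shared across the package."""


class DualSipError(Exception):
    """Base class for all package errors."""


class InputFormatError(DualSipError):
    """A file or table violates the expected format."""


class ParameterError(DualSipError):
    """A parameter is outside its valid domain."""


class UndefinedResultError(DualSipError):
    """The requested statistic is undefined for the given input
    (e.g. a weighted mean over all-zero weights)."""


class InvalidStateError(DualSipError):
    """An internally inconsistent state that should have been impossible
    given valid inputs (e.g. maximum-heavy MW not exceeding the light MW)."""
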
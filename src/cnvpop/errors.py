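"""Exception hierarchy shared across the package."""


class CnvPopError(Exception):
    """Base class for all cnvpop errors."""


class FormatError(CnvPopError):
    """A file does not conform to the expected text format."""


class ValidationError(CnvPopError):
    """An in-memory object violates a structural invariant."""


class DomainError(CnvPopError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientDataError(CnvPopError):
    """Too few observations to fit a model."""
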
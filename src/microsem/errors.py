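"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: ValidationError/FormatError -> 2,
DependencyError -> 3, ConvergenceError -> 4.
"""


class MicrosemError(Exception):
    """Base class for all package errors."""


class FormatError(MicrosemError):
    """A file could not be parsed as the declared format."""


class ValidationError(MicrosemError):
    """Input violates a declared invariant (duplicates, negative counts, ...)."""


class DependencyError(MicrosemError):
    """A pipeline stage was requested before its upstream artifacts exist."""


class ConvergenceError(MicrosemError):
    """An iterative fit failed to reach its tolerance."""
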
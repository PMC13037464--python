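"""Exception hierarchy shared across the package."""


class RedoxNicheError(Exception):
    """Base class for all package errors."""


class ParameterError(RedoxNicheError, ValueError):
    """A supplied parameter violates an invariant (message names it)."""


class ValidationError(RedoxNicheError, ValueError):
    """Input data fail a structural contract (lengths, monotonicity, ...)."""


class FormatError(RedoxNicheError, ValueError):
    """A file or string is not in a recognised format."""


class UndefinedResultError(RedoxNicheError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input."""


class PipelineError(RedoxNicheError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
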
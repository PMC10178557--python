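"""Exception hierarchy shared across the package."""


class RunSvmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RunSvmError):
    """A user-supplied parameter is outside its valid range."""


class ValidationError(RunSvmError):
    """A dataset violates an invariant (e.g. a class with < 2 samples)."""


class ParseError(RunSvmError):
    """A file could not be parsed; the message names the offending cell."""


class ContractError(RunSvmError):
    """An internal pre-condition was violated by a caller."""


class EvaluationError(RunSvmError):
    """An objective function returned a non-finite value."""
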
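"""Exception hierarchy for gemqc."""


class GemqcError(Exception):
    """Base class for all gemqc errors."""


class FormatError(GemqcError):
    """A file could not be parsed; the message names the offending element."""


class ModelValidationError(GemqcError):
    """A model violates one of its structural invariants."""


class CapabilityError(GemqcError):
    """A requested output dialect cannot represent a model feature."""


class ConfigurationError(GemqcError):
    """An operation was invoked without required configuration (e.g. no objective)."""


class UnknownIdentifierError(GemqcError):
    """An operation referenced an identifier absent from the model."""


class InfeasibleError(GemqcError):
    """A linear program that must be feasible for the operation was not."""


class SolverError(GemqcError):
    """The LP solver failed for a reason other than infeasibility."""
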
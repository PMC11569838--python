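"""Exception hierarchy shared across the analysis stages."""


class DuplexkitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DuplexkitError, ValueError):
    """A physical quantity is outside its meaningful domain."""


class FormatError(DuplexkitError, ValueError):
    """Malformed in-memory input (mismatched lengths, bad ordering, ...)."""


class SchemaError(DuplexkitError, ValueError):
    """A tabular file is missing a required column."""


class ParseError(DuplexkitError, ValueError):
    """A tabular file contains a cell that cannot be parsed."""


class ConfigError(DuplexkitError, ValueError):
    """A run configuration carries unknown or invalid keys."""


class InsufficientDataError(DuplexkitError, ValueError):
    """Too few observations for the requested estimate."""


class SignAnomalyError(DuplexkitError, ValueError):
    """A fitted coefficient has a physically impossible sign."""


class IdentifiabilityError(DuplexkitError, ValueError):
    """Too few data points to constrain the model parameters."""


class NoTransitionError(DuplexkitError, ValueError):
    """No interior melting transition detectable in the trace."""


class FitRejectedError(DuplexkitError, ValueError):
    """The trace is incompatible with the two-state model."""


class AnomalousMobilityError(DuplexkitError, ValueError):
    """Modified duplex migrated faster than the unmodified reference."""


class EmptySignalError(DuplexkitError, ValueError):
    """A time course carries no signal above background."""


class InputError(DuplexkitError, ValueError):
    """Inputs to a comparison are structurally incompatible."""
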
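"""Exception hierarchy."""


class RedelimError(Exception):
    """Base class for package errors."""


class ParameterError(RedelimError, ValueError):
    """Invalid parameter value."""


class DomainError(RedelimError, ValueError):
    """A point lies outside the declared domain or grid."""


class DomainEscapeError(RedelimError):
    """A trajectory left the declared domain.

    Carries the trajectory up to the last valid frame in ``last_valid``.
    """

    def __init__(self, message, last_valid=None):
        super().__init__(message)
        self.last_valid = last_valid


class HillsFormatError(RedelimError, ValueError):
    """Malformed hills file; message names the offending line."""


class SchemaError(RedelimError, ValueError):
    """Tabular input is missing required columns or keys."""


class BarrierError(RedelimError):
    """No interior barrier on a path."""


class NonConvergenceError(RedelimError):
    """Iterative procedure failed to make progress."""
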
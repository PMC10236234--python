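"""Exception types shared across the pipeline."""


class BrainageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BrainageError):
    """A configuration value is invalid; the message names the offending field."""


class RosterMismatchError(BrainageError):
    """A model was applied to data whose feature/covariate roster differs
    from the roster it was fitted with."""


class ConvergenceError(BrainageError):
    """An iterative fit failed to converge within its iteration budget."""
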
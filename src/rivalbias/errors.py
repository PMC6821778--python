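"""Exception types shared across the pipeline."""


class RivalbiasError(Exception):
    """Base class for package errors."""


class InvalidDesignError(RivalbiasError, ValueError):
    """Experimental-design counts are inconsistent or non-positive."""


class DomainError(RivalbiasError, ValueError):
    """A numeric argument lies outside its valid domain."""


class ConfigurationError(RivalbiasError, ValueError):
    """A configuration value (e.g. an unknown profile label) is invalid."""


class InsufficientDataError(RivalbiasError, ValueError):
    """Too few trials/observations for the requested operation."""


class PreconditionError(RivalbiasError, ValueError):
    """Input violates a documented precondition (e.g. unfiltered trials)."""


class EmptyInputError(RivalbiasError, ValueError):
    """An operation received an empty dataset."""


class UndefinedStatisticError(RivalbiasError, ValueError):
    """The requested statistic is undefined for this input (e.g. 0/0)."""


class ConvergenceError(RivalbiasError, RuntimeError):
    """MCMC failed the hard convergence threshold."""


class EvidenceError(RivalbiasError, ValueError):
    """Bayes-factor computation produced non-finite or degenerate densities."""
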
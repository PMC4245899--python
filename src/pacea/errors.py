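"""Exception types shared across the package."""


class PaceaError(Exception):
    """Base class for package errors."""


class ConfigurationError(PaceaError):
    """Invalid configuration input (shares, distributions, parameter files)."""


class EstimationError(PaceaError):
    """A regression model could not be estimated from the supplied data."""


class NonPositiveDefiniteError(PaceaError):
    """A covariance matrix required for sampling is not positive semi-definite."""


class ValidationError(PaceaError):
    """An assembled quantity violated a model invariant (e.g. a probability
    outside [0, 1])."""
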
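"""Exceptions and warnings shared across the package."""


class DomainError(ValueError):
    """Input outside the physical domain of the model."""


class SingularLimitError(DomainError):
    """Requested quantity diverges at the supplied parameter value."""


class InsufficientStatisticsError(RuntimeError):
    """A stochastic estimate did not accumulate enough events to be reported."""


class ModelInconsistencyWarning(UserWarning):
    """Measured inputs lie outside the region the hard-sphere model can produce."""


class LinearResponseWarning(UserWarning):
    """Driving force exceeds the linear-response regime assumed by the estimator."""
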
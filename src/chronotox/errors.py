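"""Package-wide exception hierarchy."""


class ChronotoxError(Exception):
    """Base class for all errors raised by chronotox."""


class InsufficientDataError(ChronotoxError):
    """Too few observations to fit the requested model."""


class DegenerateDesignError(ChronotoxError):
    """The design matrix is rank deficient (e.g. all samples at one phase)."""


class CalibrationError(ChronotoxError):
    """No parameter set satisfying the oscillation criteria was found."""


class IntegrationError(ChronotoxError):
    """The ODE integrator failed or produced an invalid trajectory."""
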
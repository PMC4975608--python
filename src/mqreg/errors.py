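"""Exception hierarchy for mqreg."""


class MQRegError(Exception):
    """Base class for all mqreg errors."""


class InvalidParameterError(MQRegError, ValueError):
    """A model or solver parameter is outside its admissible range."""


class SingularDesignError(MQRegError, ValueError):
    """The fixed-effects design matrix is rank deficient."""


class DegenerateScaleError(MQRegError, ValueError):
    """The robust scale estimate is zero (more than half the residuals vanish)."""


class ConvergenceError(MQRegError, RuntimeError):
    """An iterative fit did not reach its convergence criterion."""


class NotConvergedError(MQRegError, RuntimeError):
    """An operation that requires a converged fit received a non-converged one."""


class DataError(MQRegError, ValueError):
    """Input data cannot be assembled into a valid grouped dataset."""
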
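"""Exception hierarchy."""


class MicropredictError(Exception):
    """Base class for all package errors."""


class ParameterError(MicropredictError, ValueError):
    """A model parameter violates its domain (e.g. xmax <= x0, p <= 0)."""


class DomainError(MicropredictError, ValueError):
    """An input falls outside the valid domain of an operation."""


class DegenerateDataError(MicropredictError, ValueError):
    """Data carry no usable signal (flat growth curve, all-zero differences)."""


class ConvergenceError(MicropredictError, RuntimeError):
    """Nonlinear optimisation failed to converge from every start point."""
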
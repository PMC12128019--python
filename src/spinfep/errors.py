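"""Exception hierarchy."""


class SpinFepError(Exception):
    """Base class for package errors."""


class InputError(SpinFepError, ValueError):
    """Invalid user input (shapes, ranges, labels)."""


class UnsupportedBackendError(SpinFepError):
    """Operation not available for this energy backend."""


class ScheduleError(SpinFepError, ValueError):
    """Lambda windows do not tile [0, 1] contiguously."""


class DivergenceError(SpinFepError, RuntimeError):
    """Non-finite energy or force encountered during dynamics."""


class AccuracyError(SpinFepError, RuntimeError):
    """A numerical tolerance could not be met (e.g. quadrature grid too narrow)."""


class ParameterError(SpinFepError, ValueError):
    """A fixture specification cannot be realised within tolerance."""
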
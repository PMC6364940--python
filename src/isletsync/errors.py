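"""Exception types shared across the package."""


class IsletSyncError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IsletSyncError, ValueError):
    """A model or protocol parameter violates its constraints."""


class InvalidProfileError(IsletSyncError, ValueError):
    """A pulse profile is internally inconsistent (e.g. overlapping pulses)."""


class NumericError(IsletSyncError, ValueError):
    """A state variable is non-finite; the message names the offending field."""


class IntegrationError(IsletSyncError, RuntimeError):
    """The ODE solver failed; the message reports the time of failure."""


class RegimeError(IsletSyncError, ValueError):
    """Parameters fall outside the oscillatory regime of the model."""


class FlatTraceError(IsletSyncError, ValueError):
    """No oscillation detected: peak-to-trough amplitude below threshold."""


class NadirMatchingError(IsletSyncError, ValueError):
    """Perturbed and unperturbed nadirs cannot be paired unambiguously."""


class InsufficientDataError(IsletSyncError, ValueError):
    """A trace or window is too short for the requested analysis."""


class FormatError(IsletSyncError, ValueError):
    """A data file violates the expected format; names the first bad row."""
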
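"""Exception hierarchy shared across mocsim."""


class MocsimError(Exception):
    """Base class for all mocsim-specific errors."""


class InvalidParameterError(MocsimError, ValueError):
    """A parameter violates its documented precondition."""


class EmptyInputError(MocsimError, ValueError):
    """An operation received an empty collection it cannot act on."""


class InsufficientDataError(MocsimError, ValueError):
    """Fewer observations than the analysis requires."""


class DegenerateInputError(MocsimError, ValueError):
    """Input is formally valid but makes the quantity undefined (e.g. zero denominator)."""


class IncompatibleWaveformError(MocsimError, ValueError):
    """Waveforms cannot be combined (mismatched sampling or reversal potential)."""


class FitFailureError(MocsimError, RuntimeError):
    """A nonlinear fit failed to converge or the parameters are unidentifiable."""


class CalibrationError(MocsimError, RuntimeError):
    """Calibration search could not reach the requested tolerance on all targets."""
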
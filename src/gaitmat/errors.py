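"""Exception hierarchy for the gaitmat pipeline.

Every stage raises a subclass of :class:`GaitmatError` so that callers
(and the CLI) can distinguish user/data problems from programming bugs.
"""


class GaitmatError(Exception):
    """Base class for all gaitmat errors."""


class FormatError(GaitmatError):
    """A .pwm file violates the recording dialect."""


class FrameDimensionError(FormatError):
    """A frame block does not match the declared grid dimensions."""


class CalibrationError(GaitmatError):
    """Weight calibration is impossible (e.g. zero-force window)."""


class ConfigurationError(GaitmatError):
    """A simulator or pipeline configuration is invalid or infeasible."""


class InvalidPassError(GaitmatError):
    """A pass cannot be analyzed (no progression, too few boxes...)."""


class DataQualityError(GaitmatError):
    """Detected boxes are mutually inconsistent (e.g. overlapping stances)."""


class DegeneratePassError(GaitmatError):
    """Pass-level summary is undefined (zero duration, single stance)."""


class UsageError(GaitmatError):
    """An operation was called with arguments outside its contract."""


class IntegrityError(GaitmatError):
    """A tidy table violates its uniqueness or schema contract."""


class FittingError(GaitmatError):
    """A statistical model could not be estimated."""
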
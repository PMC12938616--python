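"""Exception hierarchy for the neurofeedback pipeline."""


class NfbError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NfbError, ValueError):
    """A session, cohort or scoring configuration violates its invariants."""


class InputError(NfbError, ValueError):
    """Input data is malformed (wrong shape, window out of range, empty group)."""


class FeedbackComputationError(NfbError, ArithmeticError):
    """A per-TR feedback value cannot be computed (e.g. non-positive baseline)."""


class EstimationError(NfbError, RuntimeError):
    """A statistical estimate is unavailable (singular design, too few volumes)."""


class CalibrationError(NfbError, RuntimeError):
    """Localizer calibration produced a non-positive display maximum."""


class EmptyRoiError(NfbError, RuntimeError):
    """No voxel survived the statistical threshold."""


class DegenerateDataError(NfbError, ValueError):
    """A statistic is undefined on this input (e.g. zero-variance differences)."""
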
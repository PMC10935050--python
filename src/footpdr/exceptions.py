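"""Exception hierarchy for the foot-PDR pipeline."""


class FootPdrError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FootPdrError):
    """A file does not follow the expected schema (missing columns, bad header)."""


class EmptyInputError(FootPdrError):
    """An input stream contains no samples."""


class ValidationError(FootPdrError):
    """Data violates a structural invariant (lengths, monotonic time, unit norm)."""


class ConfigurationError(FootPdrError):
    """A configuration value is out of its admissible range."""


class CalibrationError(FootPdrError):
    """A calibration window is too short or not stationary."""


class SingularSystemError(FootPdrError):
    """The per-stride linear system is singular or too ill-conditioned to solve."""


class MissingHeelStrikeError(FootPdrError):
    """An operation requiring a heel-strike index was called without one."""


class StrideSpecError(FootPdrError):
    """A synthetic stride specification describes infeasible geometry."""


class EvaluationError(FootPdrError):
    """Evaluation inputs do not align (segment/label count mismatch)."""


class MetricError(FootPdrError):
    """A stride is too short for the requested metric."""
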
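"""Exception and warning hierarchy shared across the package."""


class HasecError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(HasecError):
    """Column geometry does not define a usable separation window (e.g. VT == V0)."""


class BoundsError(HasecError):
    """A requested time window lies (partly) outside the recorded trace."""


class NoPeakError(HasecError):
    """No positive chromatographic peak could be located."""


class SingularDesignError(HasecError):
    """Regression design is singular (all x identical)."""


class NonInvertibleError(HasecError):
    """A calibration line with zero slope cannot be inverted."""


class DomainError(HasecError):
    """An argument is outside the mathematical domain of the operation."""


class CalibrationDirectionError(HasecError):
    """MW calibration slope is not negative, so retention times do not decrease with DP."""


class EmptyDistributionError(HasecError):
    """A molecular-weight distribution carries no area."""


class InsufficientDesignError(HasecError):
    """The replicate design cannot support the requested precision statistic."""


class ConfigurationError(HasecError):
    """Run configuration is missing or inconsistent."""


class GenerationError(HasecError):
    """The simulator cannot place any species inside the requested trace."""


class HasecWarning(UserWarning):
    """Base class for package warnings."""


class KavRangeWarning(HasecWarning):
    """Partition coefficient outside [0, 1]: solute fully excluded or adsorbed."""


class ExtrapolationWarning(HasecWarning):
    """A calibration is being evaluated beyond the range of its standards."""


class BelowBlankWarning(HasecWarning):
    """Predicted concentration is negative (response below the blank intercept)."""


class ClippedAreaWarning(HasecWarning):
    """Negative differential areas were clipped to zero."""


class PeakPlacementWarning(HasecWarning):
    """Simulated species elute outside the column's [t0, tT] window."""
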
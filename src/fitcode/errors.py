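"""Exception types shared across the package."""


class FitcodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSteepnessError(FitcodeError, ValueError):
    """Orientation-prior steepness a <= 1 (density would be unbounded)."""


class InvalidPriorError(FitcodeError, ValueError):
    """Density is negative somewhere or does not integrate to one."""


class DegeneratePlateauError(FitcodeError, ValueError):
    """A response function is flat on an interval where an inverse is needed."""

    def __init__(self, message, interval=None):
        super().__init__(message)
        self.interval = interval


class InvalidCDFError(FitcodeError, ValueError):
    """Cumulative values are decreasing or otherwise not a CDF."""


class ExponentRangeError(FitcodeError, ValueError):
    """An exponent lies outside its valid range."""


class InfiniteVarianceError(FitcodeError, ValueError):
    """Fisher information is zero where finite variance is required."""
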
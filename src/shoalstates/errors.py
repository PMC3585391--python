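"""Exception hierarchy shared by all shoalstates modules.

Per-frame quantities that can be undefined (e.g. polarization of a frame with
no valid fish) are signalled with ``math.nan`` rather than an exception, so
that long time series survive isolated bad frames; aggregate operations that
cannot produce a meaningful result raise one of the exceptions below.
"""


class ShoalStatesError(Exception):
    """Base class for all package errors."""


class FormatError(ShoalStatesError):
    """Input file does not follow the expected table layout."""


class EmptyInputError(ShoalStatesError):
    """Input file or sequence contains no usable records."""


class TrajectoryValidationError(ShoalStatesError):
    """Trajectory data violates a dataset invariant (e.g. out-of-tank position)."""


class ParameterError(ShoalStatesError):
    """A configuration or function parameter is outside its valid range."""


class InsufficientDataError(ShoalStatesError):
    """Not enough observations to compute the requested statistic."""


class DegenerateGeometryError(ShoalStatesError):
    """Geometry is degenerate (fewer than 3 points, or all collinear)."""


class ScriptError(ShoalStatesError):
    """A synthetic state script is inconsistent with the state regions."""
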
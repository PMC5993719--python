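"""Exception hierarchy for spheroidgeom.

All errors derive from :class:`SpheroidGeomError` (itself a ``ValueError``)
so callers can catch the package's failures with a single except clause
while still distinguishing the specific cause.
"""


class SpheroidGeomError(ValueError):
    """Base class for all spheroidgeom errors."""


class DegenerateInputError(SpheroidGeomError):
    """Input geometry is degenerate (collinear triangle, coplanar points, ...)."""


class TooFewPointsError(DegenerateInputError):
    """Not enough points to constrain the requested fit."""


class NotAnEllipsoidError(SpheroidGeomError):
    """The best-fit quadric is not an ellipsoid (indefinite or singular form)."""


class EmptyInputError(SpheroidGeomError):
    """An operation that requires at least one element received none."""
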
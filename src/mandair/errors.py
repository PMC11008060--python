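"""Exception hierarchy for mandair.

Every error raised by the package derives from :class:`MandairError` so callers
(in particular the cohort runner, which must tally per-patient exclusions) can
catch pipeline failures without masking programming errors.
"""


class MandairError(Exception):
    """Base class for all mandair errors."""


class StlFormatError(MandairError):
    """Unreadable or structurally corrupt STL file."""


class EmptyGeometryError(MandairError):
    """A mesh (or a clipped/cropped result) contains no geometry."""


class EmptyContourError(MandairError):
    """A plane does not intersect the mesh."""


class GeometryError(MandairError):
    """Invalid geometric configuration (open chains, self-intersections, ...)."""


class NonWatertightError(GeometryError):
    """A volume computation was requested on a mesh with boundary edges."""


class ConvergenceError(MandairError):
    """Iterative registration diverged."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class DegenerateFrameError(MandairError):
    """Landmarks cannot define a coordinate frame (e.g. collinear triple)."""


class InsufficientDataError(MandairError):
    """Too few points/subjects/records for the requested operation."""


class UndefinedStatisticError(MandairError):
    """A statistic is undefined for the given input (constant vector, zero
    denominator, ...)."""


class ValidationError(MandairError):
    """Input data violates a documented invariant."""
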
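"""Exception types raised across the pipeline.

Every stage raises a subclass of :class:`RpeMorphError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class RpeMorphError(Exception):
    """Base class for all package errors."""


class GeometryError(RpeMorphError):
    """A geometric construction is invalid (shell out of bounds, bad angle...)."""


class DegenerateGeometryError(GeometryError):
    """Point support is rank-deficient for the requested fit or hull."""


class PhantomError(RpeMorphError):
    """A synthetic stack cannot be generated from the given specification."""


class SpacingError(RpeMorphError):
    """Voxel spacing is missing or invalid; never silently assume isotropy."""


class ValidationError(RpeMorphError):
    """A run configuration is inconsistent (e.g. analysis window out of range)."""


class EmptyRegionError(RpeMorphError):
    """A count or percentage is undefined because the region holds no objects."""
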
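"""Exception hierarchy for perfvec.

All domain errors derive from :class:`PerfvecError` so callers (and the CLI)
can distinguish expected failures from bugs.
"""


class PerfvecError(Exception):
    """Base class for all perfvec domain errors."""


class InvalidShapeError(PerfvecError):
    """Ventricle shape parameters violate their invariants."""


class InvalidTransformError(PerfvecError):
    """Rigid-transform input is not orthonormal."""


class DegenerateGridError(PerfvecError):
    """A surface grid is empty or otherwise unusable."""


class DegenerateWeightsError(PerfvecError):
    """All area-weight products vanish; the weighted centroid is undefined."""


class ShapeMismatchError(PerfvecError):
    """Array lengths do not match the grid size."""


class FrameMismatchError(PerfvecError):
    """Two results live in different cardiac frames."""


class ParameterError(PerfvecError):
    """A scalar parameter is out of its documented range."""


class FieldOfViewError(PerfvecError):
    """The ventricle (or surface) does not fit inside the voxel grid."""


class DegenerateSamplingError(PerfvecError):
    """Every sampled weight is zero; the volume carries no signal at the surface."""


class SchemaError(PerfvecError):
    """A file or table does not match its documented schema."""


class InsufficientDataError(PerfvecError):
    """A statistical routine received too little data."""


class EmptyTableError(PerfvecError):
    """A cohort specification produces no rows."""
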
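"""Exception hierarchy.

Every failure mode named in the API contracts maps onto one of these, so
callers can catch a single base class or a specific stage failure.
"""


class CranioSpringError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(CranioSpringError):
    """Collinear/coincident landmarks or otherwise degenerate geometry."""


class EmptyResultError(CranioSpringError):
    """An operation (cut, crop, measurement) produced an empty result."""


class TopologyError(CranioSpringError):
    """Mesh topology violates an operation's requirements (non-manifold...)."""


class SeparationError(CranioSpringError):
    """Inner/outer surface separation did not yield exactly two components."""


class OffsetError(CranioSpringError):
    """Inward offset collapsed or inverted the surface."""


class ConfigurationError(CranioSpringError):
    """Invalid specification / configuration values."""


class AssemblyError(CranioSpringError):
    """FE assembly failed (unlabeled faces, missing materials)."""


class ConstraintError(CranioSpringError):
    """FE system has unconstrained rigid-body modes."""


class NonConvergenceError(CranioSpringError):
    """Newton iteration failed to reach the residual tolerance.

    Carries ``last_converged_time`` (seconds) when any step succeeded.
    """

    def __init__(self, message: str, last_converged_time: float | None = None):
        super().__init__(message)
        self.last_converged_time = last_converged_time


class ReportError(CranioSpringError):
    """A requested output (timepoint, metric) is missing from a solution."""


class MeshIOError(CranioSpringError):
    """Unreadable, empty or unsupported mesh / landmark / config file."""


class PipelineError(CranioSpringError):
    """A pipeline stage failed; message records the stage name."""
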
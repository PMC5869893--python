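"""Exception types shared across the package."""


class LexiplanError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(LexiplanError):
    """Two grids that must be identical (dims/spacing/origin) differ."""


class GeometryError(LexiplanError):
    """A phantom organ or derived structure violates a geometric requirement."""


class StructureError(LexiplanError):
    """A named structure is missing, empty, or otherwise unusable."""


class InfeasibleProblemError(LexiplanError):
    """The hard constraints of a planning problem cannot all be satisfied.

    Carries the per-constraint violation report produced by the
    feasibility subproblem.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class SolverError(LexiplanError):
    """A convex subproblem failed to converge."""

    def __init__(self, message, priority=None):
        super().__init__(message)
        self.priority = priority
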
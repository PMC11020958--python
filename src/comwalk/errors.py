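"""Exception hierarchy for comwalk."""


class ComWalkError(Exception):
    """Base class for all comwalk errors."""


class TrajectoryFormatError(ComWalkError, ValueError):
    """A trajectory file could not be parsed (missing/bad columns)."""


class ValidationError(ComWalkError, ValueError):
    """Input data violates a structural invariant (length, monotonicity, units)."""


class SegmentationError(ComWalkError, RuntimeError):
    """Step detection failed (no steps, missing interior minimum)."""


class SolverError(ComWalkError, RuntimeError):
    """A numerical solve (shooting, root finding) did not converge."""
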
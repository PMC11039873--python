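"""Exception hierarchy for the canal shape-modelling pipeline."""


class CanalSSMError(Exception):
    """Base class for all package errors."""


class MeshIOError(CanalSSMError):
    """A mesh file could not be read or written."""


class MeshValidationError(CanalSSMError):
    """A mesh violates a structural invariant (bad indices, degenerate faces, ...)."""


class NoIntersectionError(CanalSSMError):
    """A slicing plane does not intersect the mesh."""


class DegenerateSliceError(CanalSSMError):
    """A slicing plane produced an open or otherwise unusable section curve."""


class ParameterError(CanalSSMError):
    """Invalid generative or segment parameters."""


class GenerationError(CanalSSMError):
    """Cohort generation failed (e.g. truncated draws kept violating invariants)."""


class PreprocessError(CanalSSMError):
    """Mirroring / landmark extraction failed."""


class NonConvergenceError(CanalSSMError):
    """Iterative registration hit its iteration cap.

    Carries the last increments so callers can report how far from the
    stopping tolerances the run ended.
    """

    def __init__(self, message, *, iterations=None, trans_increment=None,
                 rot_increment_deg=None):
        super().__init__(message)
        self.iterations = iterations
        self.trans_increment = trans_increment
        self.rot_increment_deg = rot_increment_deg


class TopologyError(CanalSSMError):
    """Meshes expected to share a template topology do not."""


class FeatureError(CanalSSMError):
    """Feature extraction failed (too few slices, degenerate fit, ...)."""


class FitError(CanalSSMError):
    """A least-squares geometric fit failed."""
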
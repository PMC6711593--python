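"""Exception hierarchy for ssmkit."""


class SSMKitError(Exception):
    """Base class for all ssmkit errors."""


class MeshFormatError(SSMKitError, ValueError):
    """A mesh file or mesh array violates the format contract."""


class LandmarkFormatError(SSMKitError, ValueError):
    """A landmark file or landmark table violates the format contract."""


class CorrespondenceError(SSMKitError, ValueError):
    """Specimens do not share topology or landmark naming."""


class DegenerateConfigurationError(SSMKitError, ValueError):
    """Point configuration too degenerate (collinear / too few points) to align."""


class InsufficientLandmarksError(SSMKitError, ValueError):
    """Fewer observed landmarks than alignment requires."""


class ConvergenceError(SSMKitError, RuntimeError):
    """Iterative procedure failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ModelFormatError(SSMKitError, ValueError):
    """A serialized shape model is corrupt or of an unsupported version."""


class RankDeficiencyError(SSMKitError, ValueError):
    """Unregularized score solve attempted on a rank-deficient system."""


class UnknownLandmarkError(SSMKitError, KeyError):
    """A landmark name is not present in the model layout."""
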
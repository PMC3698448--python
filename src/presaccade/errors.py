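"""Exception hierarchy for the presaccade pipeline.

Every stage raises a subclass of :class:`PresaccadeError` so callers can
distinguish pipeline faults from programming errors.
"""


class PresaccadeError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(PresaccadeError):
    """Phantom shell radii are not strictly decreasing or otherwise unusable."""


class MisplacedROIError(PresaccadeError):
    """An atlas blob falls outside the gray-matter compartment."""


class InvalidMontageError(PresaccadeError):
    """Montage cannot host the requested channel layout."""


class ComponentConfigError(PresaccadeError):
    """A source component references an unknown atlas region."""


class EmptyDesignError(PresaccadeError):
    """An experiment design with zero trials was requested."""


class InvalidSignalError(PresaccadeError):
    """A trace contains NaNs or is otherwise unusable for event detection."""


class AlignmentError(PresaccadeError):
    """An ERP has the wrong time alignment for the requested measure."""


class RereferenceError(PresaccadeError):
    """Average reference requested on fewer than two channels."""


class PairingError(PresaccadeError):
    """A channel or ROI has no left/right mirror partner."""


class RegistrationError(PresaccadeError):
    """Fiducial-based electrode registration is degenerate."""


class EmptySourceSpaceError(PresaccadeError):
    """No gray-matter (or eye) voxels available to host sources."""


class GeometryError(PresaccadeError):
    """A source lies outside the region where a forward model is valid."""


class ConvergenceError(PresaccadeError):
    """Iterative forward solver failed to reach the requested residual."""


class TopologyError(PresaccadeError):
    """The conductive domain is disconnected; no unique potential exists."""


class ParameterError(PresaccadeError):
    """An invalid numeric parameter (e.g. negative regularization)."""


class RecipeError(PresaccadeError):
    """An ROI recipe references an unknown atlas label or operation."""


class EmptyROIError(PresaccadeError):
    """An ROI recipe produced an empty voxel set, or an ROI holds no nodes."""


class InsufficientDataError(PresaccadeError):
    """Too few units or cells for the requested statistical test."""


class FormatError(PresaccadeError):
    """A file on disk does not match the expected on-disk format."""


class ConfigError(PresaccadeError):
    """Pipeline configuration failed validation."""
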
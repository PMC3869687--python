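"""Exception hierarchy shared across the pipeline stages."""


class CtvbmError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(CtvbmError, ValueError):
    """Volume does not have exactly three spatial dimensions."""


class FormatError(CtvbmError, ValueError):
    """File is not a readable NIfTI-1 image."""


class DegenerateInputError(CtvbmError, ValueError):
    """Input carries no usable signal (constant, empty, all-zero...)."""


class NoBrainTissueError(CtvbmError, ValueError):
    """CT brain extraction found no voxel in the soft-tissue window."""


class SegmentationError(CtvbmError, RuntimeError):
    """Mixture fitting failed (variance collapse, no converging candidate)."""


class RegistrationError(CtvbmError, RuntimeError):
    """Spatial normalization failed (empty image, non-finite objective)."""
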
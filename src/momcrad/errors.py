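"""Exception types shared across the package."""


class MomcradError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(MomcradError, ValueError):
    """An argument violates a documented precondition."""


class EmptyRegionError(MomcradError, ValueError):
    """An analysis region has no foreground voxels."""


class DegenerateGLCMError(MomcradError, ValueError):
    """No valid voxel pairs exist at the requested offset/distance."""


class DegenerateFitError(MomcradError, ValueError):
    """A classifier fit is singular or otherwise unusable."""


class MissingModalityError(MomcradError, KeyError):
    """A fused model was asked to predict without one of its modalities."""
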
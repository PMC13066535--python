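"""Exception hierarchy for gastroflow.

All library-specific errors derive from :class:`GastroflowError` so callers
can catch pipeline failures without masking programming errors.
"""


class GastroflowError(Exception):
    """Base class for all gastroflow errors."""


class InvalidSpecError(GastroflowError, ValueError):
    """A phantom or acquisition specification violates its invariants."""


class MetadataError(GastroflowError):
    """Required image metadata (e.g. voxel spacing) is missing."""


class MultiLabelError(GastroflowError):
    """A mask file contains more than one foreground class."""

    def __init__(self, labels):
        self.labels = tuple(labels)
        super().__init__(
            f"mask contains {len(self.labels)} foreground classes "
            f"{list(self.labels)}; expected a single binary label"
        )


class InsufficientDataError(GastroflowError):
    """Too few samples inside the requested analysis window."""


class DegenerateReferenceError(GastroflowError):
    """The occlusion reference area is zero (all-empty masks)."""


class UnsupportedGeometryError(GastroflowError):
    """Slice geometry outside what an operation supports."""


class BandResolutionError(GastroflowError):
    """The spectral resolution is too coarse for the requested band."""

    def __init__(self, resolution_hz, band_width_hz):
        self.resolution_hz = resolution_hz
        self.band_width_hz = band_width_hz
        super().__init__(
            f"no spectral bins fall inside the band: resolution "
            f"{resolution_hz:.6g} Hz exceeds band width {band_width_hz:.6g} Hz; "
            f"record a longer series or widen the band"
        )


class ShapeMismatchError(GastroflowError):
    """Image and mask dimensions disagree."""

    def __init__(self, image_shape, mask_shape):
        self.image_shape = tuple(image_shape)
        self.mask_shape = tuple(mask_shape)
        super().__init__(
            f"image shape {self.image_shape} does not match mask shape "
            f"{self.mask_shape}"
        )
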
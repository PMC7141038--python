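"""Exception types raised across the package."""


class SpheromigrateError(Exception):
    """Base class for package-specific errors."""


class SpheroidGeometryError(SpheromigrateError, ValueError):
    """Requested synthetic geometry cannot fit in the image volume."""


class MultichannelImageError(SpheromigrateError, ValueError):
    """Input image has colour/sample channels; a single grayscale channel is required."""


class UnsupportedImageError(SpheromigrateError, ValueError):
    """Input image has an unsupported layout or sample format."""


class DegenerateImageError(SpheromigrateError, ValueError):
    """Automatic thresholding is impossible (e.g. constant intensity histogram)."""


class NoForegroundError(SpheromigrateError, ValueError):
    """Segmentation produced an empty foreground mask."""


class EmptyMaskError(SpheromigrateError, ValueError):
    """An operation requiring foreground voxels received an empty mask."""
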
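"""Exception types shared across the pipeline."""


class NetquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetquantError):
    """Input image has an unsupported layout (e.g. RGB without a channel selector)."""


class ConfigurationError(NetquantError):
    """A requested configuration is unsatisfiable (e.g. ROI larger than the image)."""


class PlacementError(NetquantError):
    """Random placement failed within the attempt budget."""


class DegenerateHistogramError(NetquantError):
    """Automatic thresholding received a constant image."""


class DegenerateDataError(NetquantError):
    """A statistical routine received data with no variance where variance is required."""
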
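"""Exception types shared across the pipeline."""


class FluorogradeError(Exception):
    """Base class for package-specific errors."""


class FormatError(FluorogradeError):
    """A file exists but its content violates the expected raster format."""


class DegenerateInputError(FluorogradeError):
    """Input carries no usable signal (e.g. a constant image for Otsu)."""


class ConfigurationError(FluorogradeError):
    """A parameter combination is internally inconsistent."""


class UndefinedMetricError(FluorogradeError):
    """A metric is requested on data where it is mathematically undefined."""
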
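"""Exception hierarchy shared across the package."""


class SwathAnnotatorError(Exception):
    """Base class for all package errors."""


class ParseError(SwathAnnotatorError):
    """A spectral-library record could not be parsed."""


class ConfigurationError(SwathAnnotatorError):
    """Invalid configuration: unknown dialect, adduct, polarity mismatch, bad schema."""


class FormatError(SwathAnnotatorError):
    """A run file is structurally invalid (truncated mzML, MS2 scan without isolation window)."""


class UnsupportedDataError(SwathAnnotatorError):
    """Data is valid but outside scope (e.g. profile-mode spectra)."""


class InsufficientDataError(SwathAnnotatorError):
    """Too few data points for the requested computation."""


class DegenerateSpectrumError(SwathAnnotatorError):
    """A spectrum whose intensities are all zero cannot be normalised."""
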
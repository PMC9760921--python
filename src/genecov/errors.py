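"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/format problems -> 2,
I/O problems -> 3, computation failures -> 4.
"""


class GenecovError(Exception):
    """Base class for all package errors."""


class FormatError(GenecovError):
    """An input file does not conform to its expected dialect."""


class ValidationError(GenecovError):
    """Inputs are well-formed but violate a contract (range, order, unit)."""


class ConfigurationError(GenecovError):
    """Incompatible configuration, e.g. a cut-off metric vs. a table unit."""


class EmptyCatalogError(GenecovError):
    """Annotation yielded no genes after filtering."""


class EmptyTableError(GenecovError):
    """A quantification file yielded no usable records."""


class InsufficientDataError(GenecovError):
    """Too few points to fit a calibration model (n < 3)."""


class DegenerateFitError(GenecovError):
    """Regression undefined: zero variance in x or in y."""


class ConversionRefusedError(GenecovError):
    """Calibration model rejected for unit conversion (R^2 <= 0.5)."""
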
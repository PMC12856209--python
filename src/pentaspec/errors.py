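"""Exception hierarchy.

All package-specific failures derive from :class:`PentaspecError` so callers
can catch one base class; the CLI maps them to exit status 1 with a
categorized message.
"""


class PentaspecError(Exception):
    """Base class for all pentaspec errors."""


class AlphabetError(PentaspecError, ValueError):
    """Sequence contains characters outside the declared nucleic-acid alphabet."""


class DomainError(PentaspecError, ValueError):
    """Numeric argument outside its mathematical domain (e.g. f not in [0,1])."""


class FormatError(PentaspecError, ValueError):
    """Tabular input violates the expected CSV schema (missing column, bad token)."""


class ParseError(PentaspecError, ValueError):
    """A cell could not be parsed as a number; message carries the row number."""


class RangeError(PentaspecError, ValueError):
    """Requested point lies outside the data range (extrapolation, no overlap)."""


class PairingError(PentaspecError, ValueError):
    """Two traces that must match (direction, sample) do not."""


class ChannelError(PentaspecError, ValueError):
    """Spectral arithmetic attempted across incompatible channels (ABS vs CD)."""


class ParameterError(PentaspecError, ValueError):
    """Analysis parameter invalid for the data (window larger than series, ...)."""


class InsufficientDataError(PentaspecError, ValueError):
    """Too few points for the requested analysis."""


class DetectionError(PentaspecError, ValueError):
    """A downstream step requires a transition that was not detected upstream."""


class DegenerateBasisError(PentaspecError, ValueError):
    """The two CD basis spectra are (numerically) proportional; unmixing is ill-posed."""


class ConfigurationError(PentaspecError, ValueError):
    """Invalid configuration (empty template library, missing kinetics, unknown key)."""


class GridMismatchError(PentaspecError, ValueError):
    """Vectors combined pointwise are not on a common wavelength grid."""


class IntegrationError(PentaspecError, RuntimeError):
    """Kinetic integration became unstable; a smaller step is required."""
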
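"""Exception hierarchy shared across the package."""


class PoreGibbsError(Exception):
    """Base class for all package-specific errors."""


class RangeError(PoreGibbsError, ValueError):
    """An input is outside the documented validity range."""


class MissingSpeciesError(PoreGibbsError, KeyError):
    """A reaction references a species absent from the property table."""


class InsufficientDataError(PoreGibbsError, ValueError):
    """Too few observations to perform the requested computation."""


class ConfigurationError(PoreGibbsError, ValueError):
    """A required profile, field, or configuration entry is missing."""


class ParseError(PoreGibbsError, ValueError):
    """A delimited-text input could not be parsed."""
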
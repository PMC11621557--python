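"""Exception hierarchy.

Errors are split so callers can distinguish malformed inputs
(:class:`SchemaError`, :class:`ValidationError`) from mathematically
undefined index requests (:class:`UndefinedIndexError`, e.g. Igeo of a
zero concentration) and from incomplete parameter registries
(:class:`ConfigurationError`).
"""


class SoilRiskError(Exception):
    """Base class for all package errors."""


class SchemaError(SoilRiskError):
    """Input table is missing a mandatory column or carries unknown ones."""


class ValidationError(SoilRiskError):
    """A value violates a domain invariant (negative concentration, bad coordinate...)."""


class UndefinedIndexError(SoilRiskError):
    """The requested index is mathematically undefined for the given input."""


class ConfigurationError(SoilRiskError):
    """A required parameter (background, RfD, CSF, PEF...) is not configured."""
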
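"""Exception hierarchy shared across the package."""


class MapsSNError(Exception):
    """Base class for all package errors."""


class SchemaError(MapsSNError):
    """An input table does not match the expected column layout."""


class SchemeConsistencyError(MapsSNError):
    """A scoring scheme violates one of its structural invariants."""


class AuditValidationError(MapsSNError):
    """An audit value is outside the range its scheme item declares."""


class GeocodingError(MapsSNError):
    """A point could not be snapped onto the street network."""


class InsufficientDataError(MapsSNError):
    """Too few complete observations for the requested statistic."""


class UndefinedStatisticError(MapsSNError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
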
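"""Exception hierarchy.

Every error raised by this package derives from :class:`SynaptometryError`,
so callers can catch one base class. Errors that are misuse of a numeric
domain also derive from :class:`ValueError`.
"""


class SynaptometryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynaptometryError, ValueError):
    """A generator or pipeline config field is invalid; message names the field."""


class DomainError(SynaptometryError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class SizingError(SynaptometryError, ValueError):
    """A requested sample/pair count cannot be satisfied by the data."""


class InsufficientDataError(SynaptometryError, ValueError):
    """Too few observations to compute the requested statistic."""


class DataError(SynaptometryError, ValueError):
    """Malformed tabular input (e.g. duplicate spine ids)."""


class GeometryError(SynaptometryError, ValueError):
    """Degenerate geometry (e.g. coplanar region given to a hull)."""


class MeshError(SynaptometryError, ValueError):
    """A mesh fails a structural requirement (e.g. not watertight)."""


class TaggingError(SynaptometryError, KeyError):
    """A named triangle region is missing from a tagged mesh."""


class ConsistencyError(SynaptometryError, ValueError):
    """Measurements contradict each other (e.g. whole-spine < head volume)."""


class UnitError(SynaptometryError, ValueError):
    """Units of two inputs cannot be reconciled."""
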
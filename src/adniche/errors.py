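"""Exception hierarchy shared across the package."""


class AdNicheError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AdNicheError, ValueError):
    """A value violates an operation's preconditions."""


class FormatError(AdNicheError, ValueError):
    """A file does not conform to the expected tabular/FASTA layout."""


class MissingMetadataError(AdNicheError, KeyError):
    """A sample referenced by the data has no metadata record."""


class EmptyTableError(AdNicheError, ValueError):
    """An operation left (or received) a table with no usable samples."""


class UndefinedPairError(AdNicheError, ValueError):
    """A pairwise quantity is undefined for at least one pair."""


class InvalidGroupingError(AdNicheError, ValueError):
    """A grouping has too few groups or singleton groups."""


class InsufficientSamplesError(AdNicheError, ValueError):
    """Too few samples for the requested statistic."""


class DegenerateTableError(AdNicheError, ValueError):
    """A contingency table has an all-zero row or column."""


class ConfigError(AdNicheError, ValueError):
    """An inconsistent or out-of-range configuration value."""
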
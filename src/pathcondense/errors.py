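"""Exception hierarchy for pathcondense.

Every error raised deliberately by the library derives from
:class:`PathcondenseError`, so callers (and the CLI) can separate
validation/computation failures from programming errors.
"""


class PathcondenseError(Exception):
    """Base class for all library errors."""


class GmtParseError(PathcondenseError):
    """A GMT line could not be parsed (fewer than 3 tab-separated fields)."""


class SchemaError(PathcondenseError):
    """An annotation table is missing a required column or has a bad header."""


class ValidationError(PathcondenseError):
    """A value violates a domain invariant (duplicate id, non-binary call, ...)."""


class UndefinedSimilarityError(PathcondenseError):
    """Similarity requested between two empty gene sets."""


class UndefinedOverlapError(PathcondenseError):
    """Activity overlap requested for two assays with no active compounds."""


class InsufficientInputError(PathcondenseError):
    """An operation needs more items than were provided (e.g. <2 pathways)."""


class InvalidUniverseError(PathcondenseError):
    """Background universe smaller than the union of the pathway gene sets."""


class InfeasibleConfigError(PathcondenseError):
    """Synthetic-data configuration cannot be realized (universe too small...)."""


class OracleScaleError(PathcondenseError):
    """Exhaustive oracle invoked above its enumeration bound."""


class EmptyQueryError(PathcondenseError):
    """Enrichment query is empty after intersection with the universe."""


class InsufficientPairsError(PathcondenseError):
    """Fewer than 3 usable assay pairs for a correlation."""


class DegenerateCorrelationError(PathcondenseError):
    """Zero variance in gene sharing or activity overlap across pairs."""
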
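"""Exception hierarchy for the phenome-scan engine.

Every error raised by the package derives from :class:`PhenoscanError`
so callers can catch the whole family at the scan boundary.
"""


class PhenoscanError(Exception):
    """Base class for all phenoscan errors."""


class MalformedColumn(PhenoscanError):
    """A phenotype column header does not match ``x<field>_<instance>_<array>``."""


class SchemaError(PhenoscanError):
    """A metadata file is missing a required column."""


class DuplicateField(PhenoscanError):
    """The variable-information file lists a field id more than once."""


class InvalidReassignment(PhenoscanError):
    """A data-coding reassignment chains (a=b and b=c) or is malformed."""


class DuplicateParticipant(PhenoscanError):
    """A participant id occurs more than once within one input file."""


class EmptyJoin(PhenoscanError):
    """No participant id is shared across the supplied input files."""


class AmbiguousSingle(PhenoscanError):
    """A categorical (single) field presents more than one array column."""


class MissingDataCode(PhenoscanError):
    """A categorical (single) field has no resolvable data coding."""


class DegenerateDistribution(PhenoscanError):
    """A vector has too few distinct non-missing values to transform."""


class DegenerateExposure(PhenoscanError):
    """The trait of interest is constant on the complete cases."""


class DegenerateOutcome(PhenoscanError):
    """A binary outcome has a single class on the complete cases."""


class EmptyExpansion(PhenoscanError):
    """A categorical (multiple) field has no non-negative value to expand."""


class CategoryLimitExceeded(PhenoscanError):
    """An unordered outcome exceeds the category limit for multinomial fits."""


class NoTests(PhenoscanError):
    """Ranking was requested but no countable test produced a p-value."""


class InvalidHierarchy(PhenoscanError):
    """The category hierarchy is not a tree (cycle or multiple roots)."""


class ConfigError(PhenoscanError):
    """A run or simulation configuration value is invalid."""
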
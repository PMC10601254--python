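"""Exception hierarchy.

``DataError`` flags problems with the observed table (degenerate
contingency tables, empty groups); ``ConfigurationError`` flags bad
analysis settings.  Plain ``ValueError`` is used for API misuse.
"""


class CohortBNError(ValueError):
    """Base class for package errors."""


class DataError(CohortBNError):
    """The data cannot support the requested computation."""


class ConfigurationError(CohortBNError):
    """An analysis setting (kind map, alpha, k, ...) is invalid."""
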
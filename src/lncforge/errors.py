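"""Exception hierarchy for the pipeline.

Every error raised on bad user input derives from :class:`LncforgeError` so a
CLI wrapper can catch one type and exit cleanly.
"""


class LncforgeError(Exception):
    """Base class for all package errors."""


class ParseError(LncforgeError):
    """A file could not be parsed (message names the file and line)."""


class DataError(LncforgeError):
    """Input parsed but violates a data invariant (negative count, missing vote...)."""


class ConfigurationError(LncforgeError):
    """Inconsistent configuration (unknown sample, empty selection, bad keywords...)."""


class GenerationError(LncforgeError):
    """The synthetic-data generator was asked for an infeasible layout."""


class EstimationError(LncforgeError):
    """A statistical estimator cannot be computed from the given data."""
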
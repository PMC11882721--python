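"""Exception hierarchy shared across the pipeline."""


class OrthoconserveError(Exception):
    """Base class for all package errors."""


class FormatError(OrthoconserveError, ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(OrthoconserveError, ValueError):
    """Input values violate a documented precondition."""


class DegenerateTableError(OrthoconserveError, ValueError):
    """A contingency table has a zero margin where the test is undefined."""


class DegenerateDistributionError(OrthoconserveError, ValueError):
    """A distribution has zero spread where a z-score is undefined."""
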
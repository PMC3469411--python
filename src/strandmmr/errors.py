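"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed inputs (bad sequences, inconsistent
records, invalid configuration); ``EstimatorError`` covers statistical
preconditions that data can fail at run time (e.g. the p0 estimator on data
without zero-count cultures). The CLI maps these to distinct exit codes.
"""


class StrandMmrError(Exception):
    """Base class for package-specific errors."""


class ValidationError(StrandMmrError, ValueError):
    """Invalid input data or configuration."""


class EstimatorError(StrandMmrError, RuntimeError):
    """A statistical estimator's preconditions are not met by the data."""
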
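"""Exception hierarchy for fnclasso.

All errors derive from :class:`FncLassoError` so callers can catch the
package's failures with a single except clause.
"""


class FncLassoError(Exception):
    """Base class for all fnclasso errors."""


class InvalidInputError(FncLassoError, ValueError):
    """Malformed or out-of-contract input (empty vectors, bad ranges...)."""


class DegenerateSignalError(FncLassoError):
    """The signal-count estimate is zero: FNP screening is meaningless."""


class DegenerateFitError(FncLassoError):
    """The regression target carries no information (constant phenotype)."""


class AlignmentError(FncLassoError):
    """Base and target SNP identifiers cannot be reconciled."""


class LeakageError(FncLassoError):
    """Evaluation samples overlap the training samples of the model."""
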
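"""Exception hierarchy for numsense.

All numsense errors derive from :class:`NumsenseError` so callers can catch
the package's failures with a single ``except`` clause; the subclasses keep
the distinct failure modes separable.
"""


class NumsenseError(Exception):
    """Base class for all numsense errors."""


class DegenerateDesignError(NumsenseError, ValueError):
    """A stimulus design collapsed (e.g. two log-spaced levels round to the
    same integer)."""


class PlacementError(NumsenseError, RuntimeError):
    """Dot placement failed: the field cannot accommodate the requested
    numerosity without overlap within the retry budget."""


class DegenerateFitError(NumsenseError, ValueError):
    """A psychometric fit has no finite maximum-likelihood estimate
    (e.g. every response identical)."""


class InsufficientDataError(NumsenseError, ValueError):
    """Too few trials / levels / observations for the requested operation."""


class NoNormError(NumsenseError, KeyError):
    """No normative band covers the requested age."""


class CohortParseError(NumsenseError, ValueError):
    """A cohort CSV violates the schema or an invariant; carries the row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ConfigError(NumsenseError, ValueError):
    """An analysis or cohort configuration is invalid or infeasible."""


class CollinearityError(NumsenseError, ValueError):
    """Rank-deficient design matrix; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )
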
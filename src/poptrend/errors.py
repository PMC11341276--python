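"""Exception hierarchy for poptrend.

All package-specific failures derive from :class:`PoptrendError` so callers
can catch one base class at an orchestration boundary (CLI, batch scripts).
"""


class PoptrendError(Exception):
    """Base class for all poptrend errors."""


class InvalidArgumentError(PoptrendError, ValueError):
    """An argument violates a documented precondition (e.g. mass <= 0)."""


class LookupFailedError(PoptrendError, KeyError):
    """A reference-table lookup (species, class, factor) found no entry."""


class MissingDataError(PoptrendError):
    """Required information (body mass, r_max, field method) is absent."""


class FormatError(PoptrendError):
    """An input file does not conform to the documented schema."""


class MalformedRowsError(FormatError):
    """One or more data rows could not be parsed.

    Attributes
    ----------
    row_errors : list of (row_number, message)
        1-based row numbers in the source file (header excluded).
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {n}: {msg}" for n, msg in self.row_errors)
        super().__init__(f"{len(self.row_errors)} malformed row(s): {lines}")


class IneligibleSeriesError(PoptrendError):
    """A count series has fewer records than the eligibility rule allows."""

    def __init__(self, site, species, n_records, min_counts):
        self.site, self.species = site, species
        self.n_records, self.min_counts = n_records, min_counts
        super().__init__(
            f"series {site}/{species}: {n_records} record(s), "
            f"fewer than the required minimum of {min_counts}"
        )


class InvalidIntervalError(PoptrendError, ValueError):
    """A credible interval has upper bound below lower bound."""


class ModelError(PoptrendError):
    """The model cannot be built from the given series (e.g. one date)."""


class ConvergenceError(PoptrendError):
    """MCMC diagnostics indicate non-convergence.

    Carries the offending diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class ExtrapolationError(PoptrendError, ValueError):
    """A trajectory query lies outside the fitted date range."""
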
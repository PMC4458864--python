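"""Exception hierarchy for mrpool.

All package-specific errors derive from :class:`MRPoolError` so callers can
catch everything with a single except clause while still distinguishing
configuration problems from data problems.
"""


class MRPoolError(Exception):
    """Base class for all mrpool errors."""


class SchemaError(MRPoolError):
    """A required column is missing or the schema is otherwise unusable."""


class RowError(MRPoolError):
    """One or more data rows failed validation.

    Parameters
    ----------
    message : str
    rows : list of (row_number, field, detail) tuples, 1-based over data rows.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows or [])


class HarmonizationError(MRPoolError):
    """Exposure and outcome alleles for a SNP cannot be reconciled."""


class WeakInstrumentError(MRPoolError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class InputError(MRPoolError):
    """An operation received structurally invalid input (empty set, n too small...)."""


class DegenerateInputError(InputError):
    """Input is formally valid but carries no information (e.g. all P values = 1)."""
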
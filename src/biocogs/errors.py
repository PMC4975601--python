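"""Exception hierarchy.

``BiocogsError`` is the base for domain errors (CLI exit code 1);
``ConfigurationError`` covers invalid configuration (CLI exit code 2).
"""


class BiocogsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BiocogsError):
    """Invalid configuration: bad invariants, schema violations, bad units."""


class InfeasibleScheduleError(BiocogsError):
    """The required number of batches exceeds plant scheduling capacity."""

    def __init__(self, required: int, available: int):
        self.required = required
        self.available = available
        super().__init__(
            f"infeasible schedule: {required} batches/yr required but only "
            f"{available} batches/yr available at the configured occupancy, "
            f"plant days and parallel trains"
        )


class MissingPriceError(BiocogsError):
    """A demanded consumable or material has no entry in the price table."""

    def __init__(self, items):
        self.items = tuple(sorted(items))
        super().__init__("no price for demanded item(s): " + ", ".join(self.items))


class DegenerateDesignError(BiocogsError):
    """A regression design matrix column is constant (rank deficient)."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(
            f"design matrix is rank deficient: column {column!r} is constant "
            "(a degenerate distribution collapses it)"
        )
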
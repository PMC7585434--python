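"""Exception hierarchy for stabscale.

All package-specific errors derive from :class:`StabscaleError` so callers can
catch everything from one base class while tests discriminate on subclasses.
"""


class StabscaleError(Exception):
    """Base class for all stabscale errors."""


class SchemaError(StabscaleError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(StabscaleError):
    """A value in an input table violates a domain constraint (e.g. negative cover)."""


class IncompleteWindowError(StabscaleError):
    """A site lacks one or more subplot-years inside the requested duration window."""

    def __init__(self, message: str, gaps=None):
        super().__init__(message)
        self.gaps = list(gaps) if gaps is not None else []


class SizeError(StabscaleError):
    """Fewer than the minimum number of subplots or years for a tensor."""


class DegenerateInputError(StabscaleError):
    """An input is degenerate for the requested statistic (all-zero abundances,
    zero-variance variable, single factor level...)."""


class InsufficientDataError(StabscaleError):
    """Too few observations for the requested operation (e.g. detrending < 3 years)."""


class ConfigError(StabscaleError):
    """Invalid configuration for the synthetic generator or the pipeline."""
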
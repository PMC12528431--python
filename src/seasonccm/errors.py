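"""Exception hierarchy shared across the package."""


class SeasonCCMError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SeasonCCMError, ValueError):
    """Invalid configuration value (rates, probabilities, grids)."""


class DivergenceError(SeasonCCMError, ArithmeticError):
    """A simulated trajectory left its admissible state space."""


class EmptyOutputError(SeasonCCMError, ValueError):
    """An operation produced no usable records (e.g. every survey year dropped)."""


class NoRecordsError(SeasonCCMError, ValueError):
    """No survey records matched a taxon/region/season selection."""


class DegenerateSeriesError(SeasonCCMError, ValueError):
    """A series is constant (zero variance) where variation is required."""


class ExtrapolationError(SeasonCCMError, ValueError):
    """Gap filling was asked to predict outside the observed year range."""


class InsufficientDataError(SeasonCCMError, ValueError):
    """Too few observations for the requested operation."""


class InsufficientOverlapError(InsufficientDataError):
    """Two series share too few years to be compared."""
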
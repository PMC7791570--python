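"""Exception and warning types shared across the package."""


class RiskItemsError(Exception):
    """Base class for package errors."""


class ConfigurationError(RiskItemsError, ValueError):
    """Invalid configuration (fractions out of range, bad field combinations)."""


class DomainError(RiskItemsError, ValueError):
    """A response value outside its declared domain (e.g. Barratt raw not in 1..4)."""


class DegenerateInputError(RiskItemsError, ValueError):
    """Input that leaves a statistic undefined (single outcome class, empty table)."""


class DegenerateCohortWarning(UserWarning):
    """Requested cohort too small to be expected to contain both outcome classes."""
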
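"""Exception hierarchy shared across the package."""


class RefnormError(Exception):
    """Base class for all refnorm errors."""


class InvalidConfigError(RefnormError, ValueError):
    """A configuration value violates its documented invariants."""


class DesignError(RefnormError, ValueError):
    """The experimental design (day/replicate layout) is inconsistent with the data."""


class DomainError(RefnormError, ValueError):
    """A numeric input lies outside the mathematical domain of an operation."""


class SaturationError(DomainError):
    """Every droplet in a well is positive: the Poisson estimate is unbounded."""
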
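"""Exception hierarchy shared across the package."""


class AntregError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AntregError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ContractError(AntregError, ValueError):
    """Inputs violate a documented precondition (shape, coverage, pairing)."""


class ConfigurationError(AntregError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class IntegrationError(AntregError, RuntimeError):
    """The ODE solver failed or produced an unphysical state."""

    def __init__(self, message, segment=None):
        super().__init__(message)
        self.segment = segment


class SearchError(AntregError, RuntimeError):
    """An optimization run could not produce any valid candidate."""


class NoCrossingError(AntregError, ValueError):
    """A growth curve never reaches the target optical density."""

    def __init__(self, message, max_od=None):
        super().__init__(message)
        self.max_od = max_od


class DegenerateDenominatorError(AntregError, ValueError):
    """Blank-corrected OD is non-positive where a ratio is required."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = rows if rows is not None else []
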
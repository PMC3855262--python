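"""Exception hierarchy shared across the package."""


class PhenomassError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhenomassError):
    """A model or table file failed to parse in the requested dialect."""


class IntegrityError(PhenomassError):
    """Parsed content violates a structural invariant (e.g. a reaction
    references an undeclared metabolite)."""


class ConfigurationError(PhenomassError):
    """A run configuration references unknown entities or invalid values."""


class UsageError(PhenomassError):
    """An operation was called with arguments that violate its contract."""


class DataError(PhenomassError):
    """An experiment record is missing required fields."""


class SolverError(PhenomassError):
    """An LP/MILP solve failed unexpectedly."""
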
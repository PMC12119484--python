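"""Exception hierarchy shared across the package."""


class EquiallocError(Exception):
    """Base class for package errors."""


class ConfigurationError(EquiallocError, ValueError):
    """An invalid configuration field; the message names the field."""


class DataError(EquiallocError, ValueError):
    """Input data violate a contract (schema, finiteness, ordering)."""


class DomainError(EquiallocError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UndefinedMetricError(EquiallocError, ValueError):
    """A metric has no defined value on the given data (e.g. no comparable pairs)."""


class UnfitError(EquiallocError, ValueError):
    """A model cannot be fitted on the given data (e.g. zero observed events)."""


class FeasibilityError(EquiallocError, ValueError):
    """A plan violates its budget constraint."""
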
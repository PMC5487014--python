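"""Exception and warning types shared across the pipeline."""


class DataplanError(Exception):
    """Base class for all dataplan errors."""


class ValidationError(DataplanError):
    """Malformed or out-of-range input data (bad CSV cell, duplicate timestamp...)."""


class SchemaError(DataplanError):
    """Structurally incompatible inputs (missing columns, item sets that don't line up)."""


class IdentifierMismatchError(SchemaError):
    """Factor/item identifier sets disagree between two objects that must align."""


class EmptyModelError(DataplanError):
    """A model with zero factors or zero items was supplied where one is required."""


class DegenerateSeverityError(DataplanError):
    """All item means are zero, so severity cannot be normalized."""


class ConditioningError(DataplanError):
    """Singular or near-singular matrix; carries the offending item names when known."""

    def __init__(self, message: str, items: list | None = None):
        super().__init__(message)
        self.items = list(items) if items else []


class ConvergenceError(DataplanError):
    """Iterative estimation failed to converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StationarityError(DataplanError):
    """Lag-1 path matrix has spectral radius >= 1; the process would diverge."""


class SampleSizeError(DataplanError):
    """Too few usable observations (or lag pairs) for the requested model."""


class DegenerateInputWarning(UserWarning):
    """All-zero score vector normalized to all zeros instead of dividing by zero."""


class SerialDependenceWarning(UserWarning):
    """Chi-square based fit indices assume independent rows; EMA occasions are serially
    dependent, so the indices are approximate."""
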
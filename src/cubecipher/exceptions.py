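"""Exception hierarchy shared across the package."""


class CubeCipherError(Exception):
    """Base class for all package errors."""


class ValidationError(CubeCipherError, ValueError):
    """An input violates a documented precondition (bad key, shape, range)."""


class IntegrityError(CubeCipherError):
    """A persisted cipher record fails its checksum or format check."""


class UndefinedMetricError(CubeCipherError, ArithmeticError):
    """A metric is mathematically undefined for the given inputs
    (zero variance for a correlation, zero denominator for structural content).
    """


class CapacityError(CubeCipherError, MemoryError):
    """The requested full cube exceeds the configured memory cap."""
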
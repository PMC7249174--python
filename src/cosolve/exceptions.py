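"""Exception hierarchy for cosolve.

All errors raised on bad user input derive from :class:`CosolveError`,
which itself derives from :class:`ValueError` so callers can catch either.
"""


class CosolveError(ValueError):
    """Base class for all cosolve input and domain errors."""


class InvalidInputError(CosolveError):
    """A scalar argument violates its physical domain (mass < 0, T <= 0, ...)."""


class SchemaError(CosolveError):
    """A tabular input is missing required columns or has unparseable cells."""


class DuplicateKeyError(CosolveError):
    """Two rows share the same (composition, temperature) key."""


class RangeError(CosolveError):
    """A solubility value lies outside the open interval (0, 1)."""


class OutOfDomainError(CosolveError):
    """A quantity was requested outside the model's domain (e.g. T > T_fus)."""


class InsufficientDataError(CosolveError):
    """Too few distinct points to fit the requested model."""


class MissingEndpointError(CosolveError):
    """A mixture model needs both pure-solvent series and one is absent."""


class DegenerateRegressionError(CosolveError):
    """The regressor has no variance; the slope is undefined."""
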
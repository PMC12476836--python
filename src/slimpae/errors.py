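"""Exception hierarchy for slimpae.

All package-specific failures derive from :class:`SlimPAEError` so callers can
catch one base class; subclasses also inherit the closest builtin (ValueError,
KeyError, OSError) so idiomatic handling keeps working.
"""


class SlimPAEError(Exception):
    """Base class for all slimpae errors."""


class ScoreParseError(SlimPAEError, ValueError):
    """A score/confidence file is malformed or missing a required key."""


class DimensionMismatchError(SlimPAEError, ValueError):
    """Array/partition dimensions are inconsistent (e.g. sum of chain lengths
    does not equal the PAE matrix dimension)."""


class MissingPartitionError(SlimPAEError, ValueError):
    """Chain boundaries could not be derived and were not supplied."""


class BundleIncompleteError(SlimPAEError, FileNotFoundError):
    """An AF3-server output bundle lacks a required member file."""


class ChainCountError(SlimPAEError, ValueError):
    """An operation requiring exactly two chains got a different count."""


class ChainLookupError(SlimPAEError, KeyError):
    """A chain label is not present in the record's partition."""


class DomainError(SlimPAEError, ValueError):
    """A numeric argument lies outside the operation's domain."""


class DegenerateInputError(SlimPAEError, ValueError):
    """Input is structurally valid but degenerate for the operation
    (empty pool, all-zero values, empty score class, ...)."""


class SamplingError(SlimPAEError, ValueError):
    """A subsample request exceeds what the pool can provide."""


class FitFailureError(SlimPAEError, RuntimeError):
    """Non-linear least squares failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnderdeterminedError(SlimPAEError, ValueError):
    """Fewer fit points than the model can be identified from."""


class MethodMismatchError(SlimPAEError, ValueError):
    """Motif calls produced by different methods were mixed where a single
    scoring convention is required."""


class ExhaustionError(SlimPAEError, ValueError):
    """Not enough admissible shuffled pairs to satisfy the request."""

    def __init__(self, message: str, admissible: int = 0):
        super().__init__(message)
        self.admissible = admissible


class FixtureSpecError(SlimPAEError, ValueError):
    """A synthetic fixture specification is internally inconsistent."""
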
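"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: schema errors -> 2, convergence
errors -> 3, invalid geometry / configuration -> 4.
"""


class ScallopSizeError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(ScallopSizeError):
    """Camera/footprint geometry is physically impossible (non-positive
    altitude, tilt pushing an edge ray past the horizon, zero pixels)."""


class UnderdeterminedFitError(ScallopSizeError):
    """A regression cannot be identified from the data supplied
    (too few points, rank-deficient design, zero variance)."""


class ConvergenceError(ScallopSizeError):
    """Likelihood optimization failed to converge from every start."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(ScallopSizeError):
    """A delimited-text table violates its schema (missing column,
    unparseable value, duplicated key); names the offending column/row."""


class IncompatibilityError(ScallopSizeError):
    """Two objects that must share structure (bin edges, grid/model
    dimensions) do not."""


class JoinError(ScallopSizeError):
    """An annotation references an image with no metadata record."""


class ExcludedRecordError(ScallopSizeError):
    """A record is excluded by protocol (e.g. partially visible shell)."""
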
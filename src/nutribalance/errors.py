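"""Exception hierarchy for nutribalance.

All package errors derive from :class:`NutribalanceError` so callers can
catch one base class. Data-quality problems (non-positive parts, label
mismatches, degenerate samples) are separated from configuration problems
so the CLI can map them to distinct exit codes.
"""


class NutribalanceError(Exception):
    """Base class for all nutribalance errors."""


class ConfigError(NutribalanceError):
    """Invalid configuration (bad flag value, unreadable path, bad α)."""


class DataError(NutribalanceError):
    """Invalid or degenerate input data."""


class DimensionError(DataError):
    """Wrong number of parts, rows, or coordinates."""


class PositivityError(DataError):
    """A compositional part is zero or negative."""


class FillingValueError(DataError):
    """Measured parts already meet or exceed the closure constant."""


class LabelError(DataError):
    """Unknown, duplicated, or mismatched part labels."""


class HierarchyViolationError(DataError):
    """A contrast matrix is not a sequential binary partition."""


class UnitMismatchError(DataError):
    """Operands carry different closure constants or units."""


class DegenerateSampleError(DataError):
    """A sample has zero variance or too few observations for a test."""


class InsufficientDataError(DataError):
    """Not enough rows for the requested estimator."""


class DegenerateCovarianceError(DataError):
    """A scatter matrix is singular (collinear variables)."""


class PipelineError(NutribalanceError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
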
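"""Exception hierarchy shared by all analysis stages."""


class AnalysisError(Exception):
    """Base class for every error raised by this package."""


class SchemaError(AnalysisError):
    """A table is missing, or has renamed, one of its required columns."""


class TableParseError(AnalysisError):
    """A cell could not be parsed; carries the 1-based data-row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyTableError(AnalysisError):
    """A table contained a header but no data rows."""


class InvariantError(AnalysisError, ValueError):
    """A domain value violates a type invariant (sign, ordering, finiteness)."""


class ParameterError(AnalysisError, ValueError):
    """A model parameter is outside its admissible range."""


class UnknownCompoundError(AnalysisError, KeyError):
    """A compound name is absent from the registry."""


class FitError(AnalysisError):
    """A regression or nonlinear fit failed or is ill-conditioned."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class DataQualityError(AnalysisError):
    """Measurements contradict the model's premises (e.g. enhancement where
    quenching is required)."""


class BracketingError(AnalysisError):
    """Interpolation target is not bracketed by the data."""


class NotApplicableError(AnalysisError):
    """An operation was requested for a classification that does not define it."""
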
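"""Exception types shared across the pipeline."""


class SomTaskError(Exception):
    """Base class for all package errors."""


class DesignError(SomTaskError, ValueError):
    """Invalid task-design request (e.g. cell counts cannot be balanced)."""


class ParameterError(SomTaskError, ValueError):
    """Parameter outside its admissible range."""


class InvalidStateError(SomTaskError, ValueError):
    """An internal task state (e.g. rating marker) violates its invariant."""


class FitError(SomTaskError, RuntimeError):
    """Model fitting failed on every start point."""


class UnderdeterminedDesignError(SomTaskError, ValueError):
    """Too few included trials to estimate the requested design."""


class DegenerateDesignError(SomTaskError, ValueError):
    """A design column has zero variance over the included trials."""


class ValidationError(SomTaskError, ValueError):
    """External data violates the trial-table schema; carries row diagnostics."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []
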
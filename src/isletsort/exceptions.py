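"""Exception types shared across the package."""


class IsletError(Exception):
    """Base class for all isletsort errors."""


class TableFormatError(IsletError, ValueError):
    """A cell table is malformed (missing column, bad value, unknown type)."""


class ValidationError(IsletError, ValueError):
    """An in-memory object violates its invariants."""


class ConfigError(IsletError, ValueError):
    """A configuration value is outside its admissible range."""


class TuningError(IsletError, RuntimeError):
    """Contact-threshold tuning could not reach the degree target.

    Carries the best candidate found so callers can inspect how close it got.
    """

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class DegenerateLikelihoodError(IsletError, RuntimeError):
    """Every sampled attraction set received zero likelihood."""
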
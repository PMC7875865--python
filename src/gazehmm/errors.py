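"""Exception hierarchy shared across the pipeline."""


class GazeHMMError(Exception):
    """Base class for all package errors."""


class FormatError(GazeHMMError):
    """A file does not conform to the documented schema (missing column, bad value)."""


class IntegrityError(GazeHMMError):
    """Data violate an internal consistency rule (duplicates, overlapping AOIs)."""


class BoundsError(GazeHMMError):
    """A coordinate falls outside its canvas."""


class InfeasibleError(GazeHMMError):
    """Too little data for the requested model size."""


class DegenerateModelError(GazeHMMError):
    """Numerical degeneracy during likelihood evaluation or EM (collapsed variance)."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class ScanError(GazeHMMError):
    """Every restart failed for some state count during a model scan."""


class UsageError(GazeHMMError):
    """Inconsistent arguments (model/sequence mismatch, undefined linkage)."""


class DesignError(GazeHMMError):
    """An unbalanced or incomplete factorial layout where balance is required."""


class StageError(GazeHMMError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
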
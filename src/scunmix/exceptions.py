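"""Exception hierarchy for scunmix.

All scunmix errors derive from :class:`ScunmixError` so callers can catch
pipeline failures with a single except clause.
"""


class ScunmixError(Exception):
    """Base class for all scunmix errors."""


class MatrixParseError(ScunmixError):
    """A cell of an input matrix could not be parsed as a number."""


class ValidationError(ScunmixError):
    """Input violates a structural contract (duplicate ids, bad shapes...)."""


class InsufficientDataError(ScunmixError):
    """Too few samples or points for the requested operation."""


class NormalizationStateError(ScunmixError):
    """Operation applied in the wrong normalization state."""


class DegenerateBlockError(ScunmixError):
    """A feature block has zero pooled standard deviation."""


class ParameterError(ScunmixError):
    """A numeric parameter is outside its documented range."""


class UndefinedMetricError(ScunmixError):
    """A similarity metric is undefined for the given input sizes."""


class StageError(ScunmixError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        full = f"[{stage}] {message}"
        if hint:
            full += f" (hint: {hint})"
        super().__init__(full)
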
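"""Exception hierarchy shared across the package."""


class ImatnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ImatnetError, ValueError):
    """A parameter is outside its documented range."""


class ValidationError(ImatnetError, ValueError):
    """A table violates a structural invariant (duplicate ids, bad labels...)."""


class ParseError(ImatnetError, ValueError):
    """A file could not be parsed into the expected table shape."""


class AlignmentError(ImatnetError, ValueError):
    """Expression matrix and clinical table share no participants."""


class DegenerateInputError(ImatnetError, ValueError):
    """An input has zero variance where variation is required."""


class CollinearityError(ImatnetError, ValueError):
    """Muscle and IMAT predictors are numerically collinear for a gene."""


class ConsistencyError(ImatnetError, ValueError):
    """Two result objects that must refer to the same entities do not."""


class UndefinedChangeError(ImatnetError, ZeroDivisionError):
    """Relative change requested with a zero baseline."""


class InfiniteStatisticError(ImatnetError, FloatingPointError):
    """A test statistic is infinite (zero-variance differences, nonzero mean)."""


class PipelineStageError(ImatnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
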
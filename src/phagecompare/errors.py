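"""Exception hierarchy shared across the package."""


class PhagecompareError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhagecompareError):
    """A file or string does not conform to the expected format."""


class CoordinateError(FormatError):
    """Feature coordinates violate the 1-based inclusive convention."""


class AlphabetError(PhagecompareError):
    """A sequence contains characters outside the allowed alphabet."""


class AlignmentError(PhagecompareError):
    """Alignment or alignment-derived computation failed."""


class TreeError(PhagecompareError):
    """Tree construction or tree-statistic computation failed."""


class GeneratorError(PhagecompareError):
    """Synthetic-community generation failed."""


class PipelineError(PhagecompareError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
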
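"""Exception hierarchy shared across the package."""


class VgZincError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(VgZincError):
    """An input file or collection contained no usable records."""


class MalformedAlignmentError(VgZincError):
    """Alignment records are not all the same length."""


class UnknownReferenceError(VgZincError, KeyError):
    """A sequence accession is not present in the alignment."""


class FormatError(VgZincError):
    """A structure or table file could not be parsed in the named dialect."""


class MissingResidueError(VgZincError, KeyError):
    """A residue number is absent from the structure."""


class AlignmentMismatchError(VgZincError):
    """Conservation-profile numbering disagrees with the structure sequence."""


class InsufficientBlanksError(VgZincError):
    """Fewer than two blank samples; a blank SD cannot be computed."""


class GenerationError(VgZincError):
    """Synthetic-structure packing failed after bounded retries."""


class PipelineError(VgZincError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
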
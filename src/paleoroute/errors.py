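"""Exception hierarchy shared across the pipeline."""


class PaleorouteError(Exception):
    """Base class for all package errors."""


class FormatError(PaleorouteError):
    """A file is structurally invalid for its declared format."""


class DuplicateIdError(FormatError):
    """An identifier that must be unique appears more than once."""


class NewickParseError(FormatError):
    """Malformed Newick text.

    Attributes
    ----------
    offset : int
        0-based character offset of the first offending character,
        or -1 when the position could not be located.
    """

    def __init__(self, message: str, offset: int = -1):
        super().__init__(message)
        self.offset = offset


class ValidationError(PaleorouteError):
    """A domain-type invariant is violated."""


class InsufficientReferenceError(PaleorouteError):
    """Too few accepted orthologues to compute a stable distance threshold."""


class ConstraintConflictError(PaleorouteError):
    """Timescaling produced a node age violating a calibration maximum."""


class TopologyMismatchError(PaleorouteError):
    """Two trees expected to share a topology do not."""


class StageError(PaleorouteError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
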
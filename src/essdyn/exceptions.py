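"""Exception hierarchy shared across the pipeline."""


class EssdynError(Exception):
    """Base class for all package errors."""


class StructuralError(EssdynError):
    """A coordinate file violates structural expectations (e.g. missing CA)."""


class ConsistencyError(EssdynError):
    """Frames or replicas disagree on residue content or metadata."""


class FormatOverflowError(EssdynError):
    """A value cannot be represented in a fixed-width file format."""


class InsufficientPointsError(EssdynError):
    """Too few points for a well-posed superposition."""


class DataError(EssdynError):
    """Non-finite or otherwise invalid numeric input."""


class AlignmentError(EssdynError):
    """Per-frame labels of two inputs cannot be matched one-to-one."""


class DegeneracyError(EssdynError):
    """Geometrically degenerate input (e.g. collinear score points)."""


class DegenerateTestError(EssdynError):
    """A statistical test is undefined for the given counts."""


class StageError(EssdynError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
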
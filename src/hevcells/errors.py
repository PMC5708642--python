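"""Exception hierarchy shared across the pipeline stages."""


class HEVCellsError(Exception):
    """Base class for all package errors."""


class FormatError(HEVCellsError):
    """Input image/array has the wrong shape, dtype or channel count."""


class InvalidStainVectorsError(HEVCellsError):
    """Stain matrix is singular or malformed."""


class NoTissueError(HEVCellsError):
    """Image contains no detectable stained tissue."""


class DegenerateThresholdError(HEVCellsError):
    """Histogram has no contrast; a global threshold is undefined."""


class ParameterError(HEVCellsError):
    """A pipeline parameter is out of its documented range."""


class EmptyPartitionError(HEVCellsError):
    """Watershed was asked to partition a mask with no seeds."""


class EmptyRegionError(HEVCellsError):
    """Feature extraction was handed an empty pixel region."""


class PairingError(HEVCellsError):
    """A virtual cell has no enclosed nucleus with a matching label."""


class InsufficientDataError(HEVCellsError):
    """Too few objects to cluster."""


class EmptyEnsembleError(HEVCellsError):
    """Ensemble selection rejected every partition."""


class StageError(HEVCellsError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {type(original).__name__}: {original}")
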
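"""Exception types shared across the pipeline stages."""


class VesselasticaError(Exception):
    """Base class for all package errors."""


class ValidationError(VesselasticaError, ValueError):
    """A spec, table or contour failed validation; message names the field."""


class SegmentationError(VesselasticaError):
    """Lumen boundary could not be identified on a frame."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class DegenerateLoopError(VesselasticaError):
    """Pressure–strain loop has no usable strain excursion."""


class ZeroBaselineError(VesselasticaError):
    """Regeneration score undefined: baseline modulus difference is zero."""


class NotCrossedError(VesselasticaError):
    """A decay series never reaches the requested threshold."""


class MissingBaselineError(VesselasticaError):
    """A cohort animal lacks the implantation-timepoint records."""

    def __init__(self, message: str, animal_id: str | None = None):
        super().__init__(message)
        self.animal_id = animal_id


class PipelineStageError(VesselasticaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
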
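"""Exception hierarchy shared across the pipeline stages."""


class OrganoidSegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OrganoidSegError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(OrganoidSegError, ValueError):
    """An image or file has an unsupported layout, depth or channel count."""


class DegenerateInputError(OrganoidSegError, ValueError):
    """Input is formally valid but degenerate for the requested operation
    (e.g. a constant image handed to Otsu thresholding)."""


class PipelineStageError(OrganoidSegError, RuntimeError):
    """A composite pipeline failed; carries the name of the failing stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")


class ModelError(OrganoidSegError, RuntimeError):
    """A segmentation model is missing, incompatible or untrained."""


class TrainingFailureError(OrganoidSegError, RuntimeError):
    """Training produced a non-finite loss; reports the epoch."""

    def __init__(self, epoch: int, message: str):
        self.epoch = epoch
        super().__init__(f"epoch {epoch}: {message}")
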
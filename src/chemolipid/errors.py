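"""Exception hierarchy for the chemogram analysis pipeline."""


class ChemolipidError(Exception):
    """Base class for all package errors."""


class FormatError(ChemolipidError):
    """Input image is not a decodable 3-channel RGB raster."""


class CalibrationError(ChemolipidError):
    """Invalid physical calibration (e.g. non-positive mm per column)."""


class RoiBoundsError(ChemolipidError):
    """Region of interest falls outside the pullback extent or is empty."""


class DimensionMismatchError(ChemolipidError):
    """Masks or images with inconsistent shapes were combined."""


class DegenerateDataError(ChemolipidError):
    """A quantity is undefined on the given data (e.g. zero valid pixels)."""


class PipelineStageError(ChemolipidError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
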
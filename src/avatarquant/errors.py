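"""Exception hierarchy shared across the pipeline stages."""


class AvatarQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(AvatarQuantError):
    """Invalid run configuration (missing channel role, bad parameter, ...)."""


class DataError(AvatarQuantError):
    """Invalid or unreadable input data."""


class DegenerateInputError(DataError):
    """Input on which the requested operation is mathematically undefined
    (e.g. Otsu thresholding of a constant volume, Z-score with zero sd)."""


class PlacementError(AvatarQuantError):
    """Synthetic phantom placement failed after bounded retries."""


class RegistrationError(DataError):
    """Image registration could not find enough inlier matches."""


class StageError(AvatarQuantError):
    """A pipeline stage failed; carries the stage name and frame index."""

    def __init__(self, stage: str, frame: int | None, cause: Exception):
        self.stage = stage
        self.frame = frame
        self.cause = cause
        where = f" at frame {frame}" if frame is not None else ""
        super().__init__(f"stage '{stage}'{where} failed: {cause}")
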
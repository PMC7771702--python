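"""Exception hierarchy used across the package."""


class SkullmarkError(Exception):
    """Base class for all package errors."""


class ConfigError(SkullmarkError):
    """Invalid configuration value (non-positive sigma, bad net size, ...)."""


class FrameError(SkullmarkError):
    """Coordinates supplied in the wrong coordinate frame."""


class InvalidInputError(SkullmarkError):
    """Degenerate or malformed array input (empty grid, bad bbox, ...)."""


class DetectionError(SkullmarkError):
    """Stage-one detector could not produce a confident skull detection."""


class ModelStateError(SkullmarkError):
    """Model used before training / loading weights."""


class AugmentationError(SkullmarkError):
    """An augmentation draw could not keep landmarks inside the crop."""


class SplitError(SkullmarkError):
    """Dataset split request that cannot be satisfied."""


class CalibrationError(SkullmarkError):
    """Invalid pixel-to-micrometre calibration."""
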
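"""Exception hierarchy for the spinemorph pipeline."""


class SpinemorphError(Exception):
    """Base class for all spinemorph errors."""


class YoloParseError(SpinemorphError, ValueError):
    """Malformed row in a YOLO-format annotation/detection file."""


class VertebraCountError(SpinemorphError, ValueError):
    """Number of boxes differs from the expected vertebra count."""


class CornerAssignmentError(SpinemorphError, ValueError):
    """A corner quadrant is empty — segmentation or smoothing is off."""


class PhantomGenerationError(SpinemorphError, ValueError):
    """Phantom geometry cannot be placed inside the image canvas."""


class CalibrationError(SpinemorphError, ValueError):
    """Area-threshold calibration received unusable training data."""
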
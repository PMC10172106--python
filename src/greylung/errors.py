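"""Exception hierarchy for the greylung pipeline."""


class GreyLungError(Exception):
    """Base class for all greylung errors."""


class FormatError(GreyLungError):
    """Unsupported image format, bit depth, or channel layout."""


class DetectionError(GreyLungError):
    """Automatic ROI landmark detection failed (flat image, all-shadow, ...)."""


class GeometryError(GreyLungError):
    """ROI geometry inconsistent with the image (band off the bottom, bad bounds)."""


class ValidationError(GreyLungError):
    """Input data violates a contract (missing baseline, mixed signals, ...)."""


class FitError(GreyLungError):
    """Non-linear regression failed to converge from every starting point."""


class CalibrationError(GreyLungError):
    """Impedance-to-volume calibration impossible (zero-variance signal)."""


class ConfigError(GreyLungError):
    """Run configuration invalid; ``violations`` lists every problem found."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
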
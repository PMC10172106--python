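"""Mean grey value (Q-LUS_MGV) quantification.

Q-LUS_MGV is the sum of the grey values of all pixels inside the pleural ROI
divided by the number of pixels — an arithmetic mean on the 8-bit scale, 0
(black) to 255 (white), in arbitrary units. Its change relative to the frame
acquired at 0 cm H2O (the start of the inflation series) is delta-MGV, the
quantity correlated with lung volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import FormatError, ValidationError

if TYPE_CHECKING:  # avoid a runtime cycle with roi (roi imports to_8bit)
    from .roi import ImageFrame, PleuralROI

__all__ = ["GreyMeasure", "to_8bit", "mgv", "delta_series"]


@dataclass
class GreyMeasure:
    """One ROI measurement: mean grey value and its baseline-relative change."""

    mgv: float                 # AU, [0, 255], full precision
    n_pixels: int
    delta_mgv: float | None = None  # mgv minus the 0 cm H2O baseline mgv
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.mgv <= 255:
            raise ValidationError("mgv outside [0, 255]")
        if self.n_pixels < 1:
            raise ValidationError("n_pixels must be >= 1")


def to_8bit(pixels: np.ndarray, source_depth: int,
            mode: str = "shift") -> np.ndarray:
    """Convert a greyscale array to 8 bits.

    8-bit input passes through unchanged. 16-bit input maps by
    ``floor(v / 256)`` (a bit shift) in the default ``shift`` mode; the
    ``rescale`` mode instead stretches the observed range linearly onto
    [0, 255], for acquisition software that does not fill the full scale.
    """
    pixels = np.asarray(pixels)
    if source_depth == 8:
        if pixels.dtype != np.uint8:
            if pixels.min() < 0 or pixels.max() > 255:
                raise FormatError("8-bit input with values outside [0, 255]")
            pixels = pixels.astype(np.uint8)
        return pixels
    if source_depth == 16:
        if mode == "shift":
            return (pixels.astype(np.uint16) >> 8).astype(np.uint8)
        if mode == "rescale":
            lo, hi = float(pixels.min()), float(pixels.max())
            if hi == lo:
                return np.zeros_like(pixels, dtype=np.uint8)
            return np.rint((pixels.astype(float) - lo) / (hi - lo) * 255
                           ).astype(np.uint8)
        raise FormatError(f"unknown conversion mode {mode!r}")
    raise FormatError(f"unsupported bit depth {source_depth}")


def mgv(frame: "ImageFrame", roi: "PleuralROI") -> GreyMeasure:
    """Mean grey value over the ROI mask, at full floating precision."""
    if roi.mask.shape != frame.shape:
        raise ValidationError("ROI mask shape does not match the frame")
    n = roi.n_pixels
    if n < 1:
        raise ValidationError("empty ROI mask")
    value = float(frame.pixels[roi.mask].sum(dtype=np.float64)) / n
    return GreyMeasure(mgv=value, n_pixels=n, meta=dict(frame.meta))


def _is_baseline(meta: dict) -> bool:
    return meta.get("limb") == "inflation" and meta.get("pressure_cmH2O") == 0


def delta_series(measures: Sequence[GreyMeasure],
                 baseline_rule=_is_baseline) -> list[GreyMeasure]:
    """Fill ``delta_mgv`` for one lamb/region series of measurements.

    The baseline is the frame selected by ``baseline_rule`` — by default the
    inflation-limb 0 cm H2O frame, where the manoeuvre starts; a deflation
    series that returns to 0 cm H2O does NOT supply the baseline. Exactly one
    baseline frame must exist.
    """
    flags = [baseline_rule(m.meta) for m in measures]
    if sum(flags) != 1:
        raise ValidationError(
            f"expected exactly one baseline frame, found {sum(flags)}")
    baseline = measures[flags.index(True)].mgv
    return [replace(m, delta_mgv=m.mgv - baseline) for m in measures]
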
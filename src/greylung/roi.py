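"""Pleural region-of-interest delineation on B-mode stills.

The ROI is a rectangular band: superior margin at the pleural line (the
bright line is inside the band), lateral margins at the rib shadows, inferior
margin a fixed depth below the pleural line — 1 mm, i.e. 50 pixels at the
default 0.02 mm/px spacing. Automatic detection finds the pleural line as
the brightest smoothed row and the rib shadows as dark column runs touching
the image flanks; a manual ROI (bounds or polygon JSON) can be imported
instead, mirroring a hand-traced workflow.

Conventions, used everywhere: rows are 0-based and half-open — the band
covers rows [pleural_row, pleural_row + depth_px); columns are 0-based and
inclusive — [left_col, right_col].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DetectionError, FormatError, GeometryError, ValidationError

__all__ = [
    "ImageFrame",
    "PleuralROI",
    "load_frame",
    "detect_pleural_line",
    "detect_rib_shadows",
    "build_roi",
    "import_manual_roi",
]


@dataclass
class ImageFrame:
    """An 8-bit greyscale still with acquisition metadata attached."""

    pixels: np.ndarray  # uint8 (rows, cols)
    pixel_spacing_mm: float = 0.02
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("frame must be a non-empty 2-D greyscale image")
        if self.pixel_spacing_mm <= 0:
            raise ValidationError("pixel_spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PleuralROI:
    """The pleural band ROI, stored both as bounds and as a boolean mask.

    Band-constructed ROIs satisfy mask.sum() == depth_px * width; polygon
    imports may carry an arbitrary mask whose bounds are its bounding box.
    """

    pleural_row: int
    left_col: int
    right_col: int
    depth_px: int
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.depth_px < 1:
            raise ValidationError("depth_px must be >= 1")
        if not self.left_col < self.right_col:
            raise ValidationError("left_col must be < right_col")
        if min(self.pleural_row, self.left_col) < 0:
            raise ValidationError("negative ROI coordinates")

    @classmethod
    def band(cls, pleural_row: int, left_col: int, right_col: int,
             depth_px: int, image_shape: tuple[int, int]) -> "PleuralROI":
        """Rectangular band fully inside an image of the given shape."""
        rows, cols = image_shape
        if pleural_row + depth_px > rows or right_col >= cols:
            raise GeometryError("band does not fit inside the image")
        mask = np.zeros(image_shape, dtype=bool)
        mask[pleural_row: pleural_row + depth_px, left_col: right_col + 1] = True
        return cls(pleural_row, left_col, right_col, depth_px, mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def width(self) -> int:
        return self.right_col - self.left_col + 1

    def to_dict(self, image: str = "", version: str = "1") -> dict:
        return {"pleural_row": int(self.pleural_row),
                "left_col": int(self.left_col),
                "right_col": int(self.right_col),
                "depth_px": int(self.depth_px),
                "image": image, "version": version}

    def save(self, path: str | Path, image: str = "") -> None:
        Path(path).write_text(json.dumps(self.to_dict(image=image)) + "\n")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_frame(path: str | Path, meta: dict | None = None,
               pixel_spacing_mm: float = 0.02,
               convert_rgb: bool = False) -> ImageFrame:
    """Read a single-channel still; 16-bit input is mapped to 8-bit.

    Multi-channel images are rejected unless ``convert_rgb`` is set, in which
    case an exactly-grey RGB image collapses to its single channel (true
    colour is refused: greyscale analysis assumes one intensity per pixel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = iio.imread(path)
    if pixels.ndim == 3:
        if not convert_rgb:
            raise FormatError(f"{path.name}: multi-channel image; "
                              "pass convert_rgb=True for grey RGB input")
        if pixels.shape[2] == 4:
            pixels = pixels[:, :, :3]
        if not (pixels[..., 0] == pixels[..., 1]).all() \
                or not (pixels[..., 0] == pixels[..., 2]).all():
            raise FormatError(f"{path.name}: true-colour image unsupported")
        pixels = pixels[..., 0]
    if pixels.dtype != np.uint8:
        from .grey import to_8bit  # local import: grey depends on roi types
        depth = 16 if pixels.dtype == np.uint16 else pixels.dtype.itemsize * 8
        pixels = to_8bit(pixels, source_depth=depth)
    return ImageFrame(pixels=pixels, pixel_spacing_mm=pixel_spacing_mm,
                      meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_pleural_line(frame: ImageFrame,
                        search_band: tuple[int, int] | None = None,
                        smooth_rows: int = 3) -> int:
    """Row of the pleural line: argmax of lightly smoothed row-mean intensity.

    ``search_band`` is a half-open [top, bottom) row interval; ties go to the
    shallower row (smaller index).
    """
    rows = frame.shape[0]
    top, bottom = search_band if search_band is not None else (0, rows)
    if not (0 <= top < bottom <= rows):
        raise ValidationError("search_band must lie inside the image")
    if frame.pixels.std() == 0:
        raise DetectionError("flat image: no pleural line to detect")
    raw = frame.pixels.mean(axis=1, dtype=float)
    smoothed = uniform_filter1d(raw, size=smooth_rows, mode="nearest")
    coarse = top + int(np.argmax(smoothed[top:bottom]))
    # refine to the raw peak within the smoothing window: the bright line
    # sits on an asymmetric background (dark tissue above, band below), so
    # the smoothed argmax can land one row deep
    half = smooth_rows // 2
    lo = max(top, coarse - half)
    hi = min(bottom, coarse + half + 1)
    return lo + int(np.argmax(raw[lo:hi]))


def detect_rib_shadows(frame: ImageFrame, pleural_row: int,
                       shadow_threshold_frac: float = 0.35,
                       ) -> tuple[int, int]:
    """Lateral ROI bounds from the dark rib-shadow runs at the image flanks.

    Column means are taken over the rows at and below the pleural line; a
    column is shadow when its mean falls below ``shadow_threshold_frac`` times
    the whole-image median (a relative threshold, robust to gain changes).
    The maximal shadow run touching each flank is excised; if a flank has no
    shadow the image edge is used and a warning emitted.
    """
    rows, cols = frame.shape
    if not 0 <= pleural_row < rows:
        raise ValidationError("pleural_row outside the image")
    col_means = frame.pixels[pleural_row:, :].mean(axis=0, dtype=float)
    threshold = shadow_threshold_frac * float(np.median(frame.pixels))
    if threshold <= 0:
        raise DetectionError("image too dark to segment rib shadows")
    is_shadow = col_means < threshold
    if is_shadow.all():
        raise DetectionError("entire image below shadow threshold")

    left_col = 0
    while is_shadow[left_col]:
        left_col += 1
    right_col = cols - 1
    while is_shadow[right_col]:
        right_col -= 1
    if left_col == 0 or right_col == cols - 1:
        warnings.warn("no rib shadow found on at least one flank; "
                      "using the image edge", stacklevel=2)
    if left_col >= right_col:
        raise DetectionError("shadow runs leave no inter-rib window")
    return left_col, right_col


def build_roi(frame: ImageFrame, pleural_row: int, left_col: int,
              right_col: int, depth_mm: float = 1.0) -> PleuralROI:
    """Assemble the band ROI; depth in mm converts to pixels via the frame's
    spacing (1.0 mm -> 50 px at 0.02 mm/px). A band running off the image
    bottom is clipped when it loses <= 10% of its rows, else it is an error."""
    if depth_mm <= 0:
        raise ValidationError("depth_mm must be positive")
    rows, _ = frame.shape
    depth_px = round(depth_mm / frame.pixel_spacing_mm)
    overhang = pleural_row + depth_px - rows
    if overhang > 0:
        if overhang > 0.1 * depth_px:
            raise GeometryError(
                f"band loses {overhang}/{depth_px} rows off the image bottom")
        warnings.warn(f"band clipped by {overhang} rows at the image bottom",
                      stacklevel=2)
        depth_px -= overhang
    return PleuralROI.band(pleural_row, left_col, right_col, depth_px,
                           frame.shape)


def detect_roi(frame: ImageFrame,
               search_band: tuple[int, int] | None = None,
               shadow_threshold_frac: float = 0.35,
               depth_mm: float = 1.0) -> PleuralROI:
    """Full automatic delineation: pleural line, rib shadows, band."""
    row = detect_pleural_line(frame, search_band)
    left, right = detect_rib_shadows(frame, row, shadow_threshold_frac)
    return build_roi(frame, row, left, right, depth_mm)


# ---------------------------------------------------------------------------
# Manual ROI import
# ---------------------------------------------------------------------------

def import_manual_roi(path: str | Path,
                      image_shape: tuple[int, int] | None = None) -> PleuralROI:
    """Load a hand-drawn ROI from JSON.

    Two schemas are accepted: four explicit bounds
    ``{pleural_row, left_col, right_col, depth_px}`` (equivalent to
    :func:`build_roi` with the same numbers), or a ``{"polygon": [[r, c],
    ...]}`` traced outline, rasterised to a mask whose bounding box supplies
    the bounds.
    """
    try:
        spec = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed ROI JSON: {exc}") from exc

    if "polygon" in spec:
        from skimage.draw import polygon as sk_polygon
        verts = np.asarray(spec["polygon"], dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValidationError("polygon must be a list of >= 3 [row, col] pairs")
        if verts.min() < 0:
            raise ValidationError("negative polygon coordinates")
        if image_shape is None:
            image_shape = (int(np.ceil(verts[:, 0].max())) + 1,
                           int(np.ceil(verts[:, 1].max())) + 1)
        rr, cc = sk_polygon(verts[:, 0], verts[:, 1], shape=image_shape)
        if rr.size == 0:
            raise ValidationError("polygon rasterises to an empty mask")
        mask = np.zeros(image_shape, dtype=bool)
        mask[rr, cc] = True
        r0, r1 = int(rr.min()), int(rr.max())
        return PleuralROI(pleural_row=r0, left_col=int(cc.min()),
                          right_col=int(cc.max()), depth_px=r1 - r0 + 1,
                          mask=mask)

    required = {"pleural_row", "left_col", "right_col", "depth_px"}
    missing = required - spec.keys()
    if missing:
        raise ValidationError(f"ROI JSON missing fields: {sorted(missing)}")
    vals = {k: int(spec[k]) for k in required}
    if min(vals.values()) < 0:
        raise ValidationError("negative ROI coordinates")
    if image_shape is None:
        image_shape = (vals["pleural_row"] + vals["depth_px"],
                       vals["right_col"] + 1)
    return PleuralROI.band(vals["pleural_row"], vals["left_col"],
                           vals["right_col"], vals["depth_px"], image_shape)
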
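"""Image loading, dish ROI detection, and median denoising.

Conventions used throughout the package
---------------------------------------
* Coordinates are ``(x, y)`` = (column, row), 0-based, with pixel centers at
  integer positions.  Numpy rasters are indexed ``[y, x]``.
* Grayscale is ITU-R BT.601 luma: ``gray = round(0.299 R + 0.587 G + 0.114 B)``,
  stored as uint8.
* Hue follows the 0-360 degree convention (HSV hue of the RGB pixel, scaled
  from skimage's [0, 1) to degrees) and is stored as a float32 raster.  All
  hue comparisons use circular distance, ``min(|a-b|, 360-|a-b|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.color import rgb2hsv

from .errors import ImageFormatError, ImageReadError, ParameterError, ROIDetectionError

__all__ = [
    "PlateImage",
    "PlateROI",
    "load_image",
    "make_plate_image",
    "detect_plate_roi",
    "roi_from_circle",
    "denoise_median",
    "circular_hue_distance",
]

#: BT.601 luma weights for the R, G, B channels.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def circular_hue_distance(a, b):
    """Circular distance between hue angles in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def circular_hue_mean(hues_deg) -> float:
    """Circular mean of hue angles in degrees, mapped into [0, 360)."""
    h = np.deg2rad(np.asarray(hues_deg, dtype=float))
    ang = np.arctan2(np.sin(h).mean(), np.cos(h).mean())
    return float(np.rad2deg(ang) % 360.0)


def region_mean_hue(rgb: np.ndarray, mask: np.ndarray) -> float:
    """Hue (degrees) of the mean RGB color over a region.

    For low-saturation regions the per-pixel hue is dominated by chroma
    noise (worst under chroma-subsampled JPEG); averaging in RGB first
    cancels the noise and recovers the underlying tint.
    """
    sel = rgb[np.asarray(mask, dtype=bool)]
    if sel.size == 0:
        return 0.0
    mean = sel.reshape(-1, 3).mean(axis=0) / 255.0
    return float(rgb2hsv(mean.reshape(1, 1, 3))[0, 0, 0] * 360.0)


@dataclass
class PlateImage:
    """A decoded plate photograph with derived grayscale and hue views."""

    rgb: np.ndarray  # H x W x 3 uint8
    gray: np.ndarray  # H x W uint8, BT.601 luma
    hue: np.ndarray  # H x W float32, degrees in [0, 360)
    source_path: str = ""

    @property
    def width(self) -> int:
        return self.rgb.shape[1]

    @property
    def height(self) -> int:
        return self.rgb.shape[0]


def make_plate_image(rgb: np.ndarray, source_path: str = "") -> PlateImage:
    """Build a :class:`PlateImage` from an 8-bit RGB array, deriving views."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
        raise ImageFormatError(
            f"expected an 8-bit RGB raster (H, W, 3) of dtype uint8, "
            f"got shape {rgb.shape} dtype {rgb.dtype}"
        )
    gray = np.rint(rgb.astype(np.float64) @ LUMA_WEIGHTS).clip(0, 255).astype(np.uint8)
    hue = (rgb2hsv(rgb)[..., 0] * 360.0).astype(np.float32)
    return PlateImage(rgb=rgb, gray=gray, hue=hue, source_path=source_path)


def load_image(path) -> PlateImage:
    """Decode a PNG/JPEG/TIFF file into a :class:`PlateImage`.

    RGBA inputs have their alpha channel dropped; any other mode (palette,
    16-bit, single channel, ...) is rejected.
    """
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode == "RGBA":
                im = im.convert("RGB")
            elif mode != "RGB":
                raise ImageFormatError(
                    f"{path}: unsupported image mode {mode!r}; "
                    "an 8-bit RGB image is required"
                )
            rgb = np.asarray(im, dtype=np.uint8)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        if isinstance(exc, ImageFormatError):
            raise
        raise ImageReadError(f"cannot read image file {path}: {exc}") from exc
    return make_plate_image(rgb, source_path=str(path))


@dataclass
class PlateROI:
    """Circular dish region of interest."""

    center_x: float
    center_y: float
    radius: float
    mask: np.ndarray = field(repr=False)  # H x W bool

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def contains(self, x: float, y: float) -> bool:
        iy, ix = int(round(y)), int(round(x))
        h, w = self.mask.shape
        return 0 <= iy < h and 0 <= ix < w and bool(self.mask[iy, ix])


def roi_from_circle(shape, cx: float, cy: float, r: float, margin: float = 0.0) -> PlateROI:
    """ROI whose mask is true exactly for pixels within ``r - margin`` of center."""
    if r <= 0:
        raise ParameterError(f"ROI radius must be positive, got {r}")
    h, w = shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    eff = max(r - margin, 0.0)
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= eff**2
    return PlateROI(center_x=float(cx), center_y=float(cy), radius=float(r), mask=mask)


def _fit_circle(xs: np.ndarray, ys: np.ndarray):
    """Algebraic (Kasa) least-squares circle fit through boundary points."""
    A = np.column_stack([2.0 * xs, 2.0 * ys, np.ones_like(xs, dtype=float)])
    b = xs.astype(float) ** 2 + ys.astype(float) ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise ROIDetectionError("degenerate circle fit")
    return float(cx), float(cy), float(np.sqrt(r2))


def detect_plate_roi(image: PlateImage, margin: float = 0.0) -> PlateROI:
    """Locate the bright circular dish against the dark surround.

    The grayscale view is thresholded (Otsu), holes are filled so colonies
    darker than the dish do not perforate the dish blob, and a least-squares
    circle is fitted to the boundary of the largest bright component.
    """
    from skimage.filters import threshold_otsu

    g = image.gray
    if int(g.max()) - int(g.min()) < 10:
        raise ROIDetectionError(
            "no circular dish structure found (image has no contrast); "
            + ROIDetectionError.hint
        )
    thr = threshold_otsu(g)
    bright = g > thr
    bright = ndimage.binary_fill_holes(bright)
    labels, n = ndimage.label(bright)
    if n == 0:
        raise ROIDetectionError("no bright region found; " + ROIDetectionError.hint)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    frame_area = g.shape[0] * g.shape[1]
    if comp.sum() < 0.05 * frame_area:
        raise ROIDetectionError(
            "largest bright region covers too little of the frame to be a dish; "
            + ROIDetectionError.hint
        )
    boundary = comp & ~ndimage.binary_erosion(comp)
    ys, xs = np.nonzero(boundary)
    cx, cy, r = _fit_circle(xs, ys)
    h, w = g.shape
    if not (-r < cx < w + r and -r < cy < h + r):
        raise ROIDetectionError("fitted dish circle lies outside the image")
    return roi_from_circle(g.shape, cx, cy, r, margin=margin)


def denoise_median(image: PlateImage, kernel: int = 3) -> PlateImage:
    """Median-filter each RGB channel with a ``kernel x kernel`` window.

    Borders are handled by edge replication.  Grayscale and hue views are
    re-derived from the filtered RGB so all views stay consistent.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ParameterError(f"median kernel must be odd and >= 3, got {kernel}")
    out = np.empty_like(image.rgb)
    for c in range(3):
        out[..., c] = ndimage.median_filter(image.rgb[..., c], size=kernel, mode="nearest")
    return make_plate_image(out, source_path=image.source_path)
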
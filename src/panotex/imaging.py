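"""Grayscale radiograph I/O, ROI cropping, gradient maps and digital zoom.

Conventions used throughout the package (stated once, here):

* Images are 2-D ``numpy`` arrays indexed ``[row, col]`` (row-major),
  0-based.
* Rectangles are half-open: ``ROIRect(row0, col0, height, width)`` covers
  rows ``row0 .. row0 + height - 1`` and columns ``col0 .. col0 + width - 1``.
* The working bit depth is 8; deeper stored data are min–max rescaled to
  [0, 255] on read with round-half-to-even.
* Digital zoom maps output pixel centres to input coordinates as
  ``x_in = (x_out + 0.5) / factor - 0.5`` per axis (the align-corners-false
  convention), so a nearest-neighbour zoom by an integer factor ``f``
  duplicates every pixel into an ``f x f`` block exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage
from skimage.transform import resize


class ZoomState(str, enum.Enum):
    NATIVE = "native"
    ZOOMED = "zoomed"


class Kernel(str, enum.Enum):
    NONE = "none"
    NEAREST = "nearest"
    BILINEAR = "bilinear"
    BICUBIC = "bicubic"


#: spline order used by the resampler for each interpolation kernel
_KERNEL_ORDER = {Kernel.NEAREST: 0, Kernel.BILINEAR: 1, Kernel.BICUBIC: 3}


class ResolutionTag(str, enum.Enum):
    """Native-resolution provenance of a radiograph."""

    R1023x496 = "1023x496"
    R1023x593 = "1023x593"
    SYNTHETIC = "synthetic"
    OTHER = "other"


@dataclass
class GrayscaleImage:
    """A 2-D grayscale radiograph (or ROI) with provenance metadata.

    Parameters
    ----------
    pixels
        2-D integer array; intensities must lie in ``[0, 2**bit_depth - 1]``.
    bit_depth
        Working bit depth (8 throughout this package).
    zoom_state, zoom_factor, kernel
        Whether and how the image was digitally magnified.
    source_resolution_tag
        Which native-resolution context the image came from.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    zoom_state: ZoomState = ZoomState.NATIVE
    zoom_factor: float = 1.0
    kernel: Kernel = Kernel.NONE
    source_resolution_tag: ResolutionTag = ResolutionTag.OTHER

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        hi = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > hi:
            raise ValueError(f"intensities must lie in [0, {hi}]")
        if self.zoom_factor < 1:
            raise ValueError("zoom_factor must be >= 1")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class ROIRect:
    """Half-open rectangular region: rows [row0, row0+height), cols [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @classmethod
    def parse(cls, text: str) -> "ROIRect":
        """Parse a ``row0,col0,height,width`` string (the CLI form)."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError("ROI must be 'row0,col0,height,width'")
        return cls(*parts)


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 255] with round-half-to-even (numpy's rint)."""
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        # constant image: map to its low byte if in range, else to 0
        v = int(lo) if 0 <= lo <= 255 else 0
        return np.full(arr.shape, v, dtype=np.uint8)
    scaled = (arr - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def read_image(path: str | Path, fmt: str | None = None) -> GrayscaleImage:
    """Read a single-frame grayscale radiograph from DICOM, PNG or TIFF.

    Stored depths above 8 bits are min–max rescaled to the 8-bit working
    depth. RGB payloads with identical channels are reduced to one channel;
    genuinely coloured or multi-frame payloads are rejected.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".dcm": "DICOM", ".png": "PNG", ".tif": "TIFF", ".tiff": "TIFF"}.get(
            suffix, "PNG"
        )
    fmt = fmt.upper()

    if fmt == "DICOM":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim == 3:
            raise ValueError("multi-frame or colour DICOM is not supported")
    elif fmt in ("PNG", "TIFF"):
        with PILImage.open(path) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise ValueError("multi-frame images are not supported")
            arr = np.asarray(im)
        if arr.ndim == 3:
            # accept grey stored as replicated RGB(A) channels
            rgb = arr[..., :3]
            if not (rgb[..., 0] == rgb[..., 1]).all() or not (
                rgb[..., 0] == rgb[..., 2]
            ).all():
                raise ValueError("colour images are not supported")
            arr = rgb[..., 0]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if arr.dtype == np.uint8:
        px = arr.copy()
    else:
        px = _rescale_to_8bit(arr)
    return GrayscaleImage(pixels=px, bit_depth=8)


def write_png(img: GrayscaleImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG. Float arrays are linearly rescaled."""
    arr = img.pixels if isinstance(img, GrayscaleImage) else np.asarray(img)
    if arr.dtype != np.uint8:
        arr = _rescale_to_8bit(arr)
    PILImage.fromarray(arr, mode="L").save(Path(path))


def crop_roi(img: GrayscaleImage, rect: ROIRect) -> GrayscaleImage:
    """Crop a rectangular ROI; provenance fields are preserved."""
    h, w = img.shape
    if rect.row0 + rect.height > h or rect.col0 + rect.width > w:
        raise ValueError(
            f"ROI {rect} exceeds image bounds {h}x{w}"
        )
    sub = img.pixels[
        rect.row0 : rect.row0 + rect.height, rect.col0 : rect.col0 + rect.width
    ].copy()
    return replace(img, pixels=sub)


def sobel_magnitude(img: GrayscaleImage) -> np.ndarray:
    """Per-pixel Sobel gradient magnitude sqrt(Gx^2 + Gy^2).

    Standard 3x3 kernels, reflect padding at the borders (avoids spurious
    edge response at the ROI frame). Returns a float array of the input
    shape; adding a constant to the image leaves the result unchanged.
    """
    px = img.pixels.astype(np.float64)
    gx = ndimage.sobel(px, axis=1, mode="reflect")
    gy = ndimage.sobel(px, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def digital_zoom(
    img: GrayscaleImage, factor: float, kernel: Kernel | str = Kernel.BILINEAR
) -> GrayscaleImage:
    """Digitally magnify by pixel interpolation.

    Output shape is ``round(factor * shape)`` per axis. Interpolated
    intensities are clipped to [0, 255] and re-quantized. ``factor`` below 1
    (downsampling) is rejected.
    """
    kernel = Kernel(kernel)
    if factor < 1:
        raise ValueError("zoom factor must be >= 1 (downsampling not supported)")
    if kernel not in _KERNEL_ORDER:
        raise ValueError(f"kernel must be one of {list(_KERNEL_ORDER)}")
    if factor == 1.0:
        out = img.pixels.copy()
    else:
        h, w = img.shape
        out_shape = (int(round(factor * h)), int(round(factor * w)))
        out = resize(
            img.pixels.astype(np.float64),
            out_shape,
            order=_KERNEL_ORDER[kernel],
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        out = np.rint(np.clip(out, 0, img.max_value)).astype(np.uint8)
    return replace(
        img,
        pixels=out,
        zoom_state=ZoomState.ZOOMED,
        zoom_factor=float(factor),
        kernel=kernel,
    )


def pixel_count(img: GrayscaleImage) -> int:
    """Total number of pixels in the ROI (height x width)."""
    h, w = img.shape
    return h * w
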
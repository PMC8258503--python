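"""Grayscale image container and TIFF/PNG input-output.

All pixel coordinates in this package are 0-based with ``x`` = column and
``y`` = row, origin at the top-left corner. Square region-of-interest (ROI)
indexing is half-open: an ROI at ``(x, y)`` of side ``s`` covers columns
``[x, x+s)`` and rows ``[y, y+s)``.

Physical pixel size is carried as metadata only; no metric in the package
depends on it. The default of 32.27 nm/px corresponds to a 128-px ROI
spanning 4.13 um, the scale at which the quantification pipeline was
designed to operate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "DEFAULT_PIXEL_SIZE_NM",
    "GrayImage",
    "read_image",
    "write_image",
    "extract_square_roi",
]

#: 128 px spanning 4.13 um.
DEFAULT_PIXEL_SIZE_NM = 4130.0 / 128.0


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale intensity grid with pixel-size metadata.

    Parameters
    ----------
    pixels
        2-D float array of intensities (arbitrary units). Physical images
        (file input, phantom output) are nonnegative; band-limited
        reconstructions, whose DC term is removed, may contain negative
        values.
    pixel_size_nm
        Edge length of one pixel in nanometres. Metadata only.
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"GrayImage requires shape >= 2x2, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("GrayImage intensities must all be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n(self) -> int:
        """Side length for square images."""
        self.require_square_even()
        return self.pixels.shape[0]

    def is_square_even(self) -> bool:
        h, w = self.pixels.shape
        return h == w and h % 2 == 0

    def require_square_even(self) -> None:
        h, w = self.pixels.shape
        if h != w or h % 2 != 0:
            raise ValueError(
                f"operation requires a square image with even side, got {h}x{w}"
            )


def _as_gray_array(arr: np.ndarray, path: Path) -> np.ndarray:
    arr = np.squeeze(arr)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: image has {arr.shape[-1]} channels; expected single-channel "
            "grayscale. Extract one channel (e.g. arr[..., 0]) and save it first."
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> GrayImage:
    """Read a single-channel grayscale TIFF or PNG into a :class:`GrayImage`.

    The TIFF X-resolution tag, when present and expressed in a physical
    unit, overrides the default pixel size; an explicit ``pixel_size_nm``
    argument overrides both.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    tag_pixel_size: float | None = None
    if suffix in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None:
                num, den = res.value
                if num > 0 and den > 0:
                    per_unit = num / den  # pixels per unit
                    unit_nm = {2: 2.54e7, 3: 1.0e7}.get(int(unit.value))  # inch, cm
                    if unit_nm is not None and per_unit > 0:
                        tag_pixel_size = unit_nm / per_unit
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = _as_gray_array(np.asarray(arr), path)
    if np.issubdtype(arr.dtype, np.floating) and np.any(arr < 0):
        raise ValueError(f"{path}: negative intensities are not a valid micrograph")
    size = pixel_size_nm if pixel_size_nm is not None else tag_pixel_size
    return GrayImage(arr.astype(float), size or DEFAULT_PIXEL_SIZE_NM)


def write_image(path: str | Path, img: GrayImage) -> None:
    """Write a GrayImage to TIFF (or PNG for 8/16-bit integral data).

    Integral data within the uint8/uint16 range round-trips bit-exactly;
    anything else is stored as 32-bit float TIFF.
    """
    path = Path(path)
    arr = img.pixels
    integral = np.all(arr == np.round(arr)) and np.all(arr >= 0)
    if integral and arr.max(initial=0) <= np.iinfo(np.uint16).max:
        out = arr.astype(np.uint8 if arr.max(initial=0) <= 255 else np.uint16)
    else:
        out = arr.astype(np.float32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        import imageio.v3 as iio

        if out.dtype == np.float32:
            raise ValueError("non-integral data must be written as TIFF")
        iio.imwrite(path, out)


def extract_square_roi(img: GrayImage, top_left: tuple[int, int], size: int) -> GrayImage:
    """Cut a ``size`` x ``size`` ROI whose top-left corner is ``(x, y)``.

    ``top_left`` follows the package convention ``(x, y)`` = (column, row);
    indexing is half-open, so the ROI covers columns ``[x, x+size)`` and
    rows ``[y, y+size)``.
    """
    x, y = top_left
    if size < 1:
        raise ValueError("ROI size must be >= 1")
    if x < 0 or y < 0 or x + size > img.width or y + size > img.height:
        max_x = img.width - size
        max_y = img.height - size
        raise ValueError(
            f"ROI (x={x}, y={y}, size={size}) exceeds image bounds "
            f"{img.width}x{img.height}; top-left must lie within "
            f"[0, {max(max_x, 0)}] x [0, {max(max_y, 0)}]"
        )
    return GrayImage(img.pixels[y : y + size, x : x + size].copy(), img.pixel_size_nm)
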
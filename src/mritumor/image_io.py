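"""Reading, writing, normalization and gray-level quantization of 2-D images.

Every other module consumes :class:`GrayImage`, a plain 2-D float array
normalized to [0, 1] at read time, so that downstream scale-sensitive
statistics (deviation/skewness shifts, fuzzy clustering on intensities,
gray-level binning) see a common intensity range regardless of the source
bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GrayImage", "QuantizedImage", "read_image", "write_image", "quantize"]

# ITU-R 601-2-ish luma weights, matching skimage.color.rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class GrayImage:
    """A 2-D grayscale image with declared intensity bounds.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of shape (rows, cols); all values finite.
    value_range : tuple of float
        Declared (lo, hi) intensity bounds; after normalization the pixel
        values lie inside this interval.
    source : str, optional
        Provenance string (file path, generator description, ...).
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)
    source: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        lo, hi = self.value_range
        if self.pixels.min() < lo - 1e-12 or self.pixels.max() > hi + 1e-12:
            raise ValueError("pixel values fall outside declared value_range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class QuantizedImage:
    """An image reduced to W discrete gray levels 0..W-1."""

    levels: np.ndarray
    W: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.W < 2:
            raise ValueError("W must be at least 2")
        if not np.issubdtype(self.levels.dtype, np.integer):
            raise ValueError("levels must be integer-valued")
        if self.levels.min() < 0 or self.levels.max() > self.W - 1:
            raise ValueError("levels must lie in [0, W-1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape


def _minmax(arr: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant array maps to all zeros."""
    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _load_raw(path: Path, mode: str, slice_index: int | None) -> np.ndarray:
    suffix = "".join(path.suffixes).lower()
    if mode == "auto":
        if suffix.endswith((".nii", ".nii.gz")):
            mode = "nifti"
        elif suffix.endswith((".dcm", ".dicom")):
            mode = "dicom"
        elif suffix.endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff")):
            mode = "png"
        else:
            raise ValueError(f"unsupported image format: {path}")
    if mode == "nifti":
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
    elif mode == "dicom":
        import pydicom

        data = pydicom.dcmread(str(path)).pixel_array
    elif mode in ("png", "tiff"):
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 3 and data.shape[-1] in (3, 4):  # RGB(A) -> luminance
            data = data[..., :3] @ _LUMA
    else:
        raise ValueError(f"unknown read mode: {mode!r}")

    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        if slice_index is None:
            raise ValueError(
                "3-D volume: pass slice_index to select a 2-D slice"
            )
        data = data[..., slice_index]
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {data.shape}")
    return data


def read_image(
    path: str | Path,
    mode: str = "auto",
    slice_index: int | None = None,
) -> GrayImage:
    """Read a grayscale image and min-max normalize it to [0, 1].

    Multi-channel inputs are converted to luminance; 3-D volumes require
    an explicit ``slice_index``. A constant image normalizes to all zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _load_raw(path, mode, slice_index)
    if not np.all(np.isfinite(raw)):
        raise ValueError(f"non-finite pixel values in {path}")
    return GrayImage(_minmax(raw), value_range=(0.0, 1.0), source=str(path))


def write_image(img: GrayImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0, 1] image as an 8- or 16-bit PNG/TIFF.

    The round trip ``read_image(write_image(x))`` preserves pixel values
    within 1/(2**bit_depth - 1).
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    import imageio.v3 as iio

    top = 2**bit_depth - 1
    scaled = np.clip(np.rint(img.pixels * top), 0, top)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), scaled.astype(dtype))


def quantize(img: GrayImage, W: int) -> QuantizedImage:
    """Bin a normalized image into W gray levels.

    level = min(floor(pixel * W), W - 1): half-open equal-width bins with
    the top-of-range pixel clamped into the last bin. Monotone in pixel
    value.
    """
    if W < 2:
        raise ValueError("W must be at least 2")
    p = img.pixels
    if p.min() < -1e-12 or p.max() > 1 + 1e-12:
        raise ValueError("image must be normalized to [0, 1] before quantization")
    levels = np.minimum(np.floor(p * W).astype(np.int64), W - 1)
    levels = np.maximum(levels, 0)
    return QuantizedImage(levels, W)
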
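"""Raster input/output and detection-window segmentation.

Scanned detection windows arrive as 8-bit RGB TIFF files (PNG is also
accepted).  Images read here are always returned as uint8 arrays of shape
(height, width, 3); 16-bit scans are rescaled to 8-bit by integer division
by 257 and grayscale images are replicated across the three channels.

Window isolation emulates interactive color thresholding: pixels are kept
if their hue falls in a circular interval around red/magenta and their
saturation exceeds a floor, and the largest 4-connected component of the
kept pixels is taken as the region of interest.  Coordinates are 0-based,
row-major, origin at the top-left.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .color import rgb_to_hsb

__all__ = [
    "WindowNotFoundError",
    "read_image",
    "write_image",
    "segment_detection_window",
    "rectangle_mask",
]

# 4-connectivity structuring element (no diagonals)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

_TIFF_SUFFIXES = {".tif", ".tiff"}


class WindowNotFoundError(RuntimeError):
    """No sufficiently large colored component was found in the image."""


def _to_uint8_rgb(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr, arr, arr], axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{source}: unsupported image layout {arr.shape}")
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.shape[-1] != 3:
        raise ValueError(f"{source}: expected 1, 3 or 4 channels, got {arr.shape[-1]}")
    if arr.dtype == np.uint8:
        return np.ascontiguousarray(arr)
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)
    raise ValueError(f"{source}: unsupported dtype {arr.dtype} (need uint8 or uint16)")


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG image as an (H, W, 3) uint8 RGB array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode == "I;16":
                arr = np.asarray(im, dtype=np.uint16)
            else:
                arr = np.asarray(im)
    return _to_uint8_rgb(arr, str(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 RGB array as TIFF or PNG (by extension).

    Round-trips losslessly: ``read_image(path)`` returns identical pixels.
    """
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8 or arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("write_image expects an (H, W, 3) uint8 array")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr, photometric="rgb")
    elif path.suffix.lower() == ".png":
        Image.fromarray(arr, mode="RGB").save(path, format="PNG")
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


def _hue_in_range(hue: np.ndarray, hue_range: tuple[float, float]) -> np.ndarray:
    lo, hi = (h % 360.0 for h in hue_range)
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    # circular interval wrapping through 0 deg, e.g. (300, 60) covers
    # magenta -> red -> orange
    return (hue >= lo) | (hue <= hi)


def segment_detection_window(
    image: np.ndarray,
    hue_range: tuple[float, float] = (300.0, 60.0),
    min_saturation: float = 5.0,
    min_area_fraction: float = 0.01,
) -> np.ndarray:
    """Isolate the colored detection window by hue/saturation thresholding.

    Pixels pass if their hue lies in ``hue_range`` (a circular interval in
    degrees; the default spans magenta through red to orange) and their
    saturation is at least ``min_saturation`` percent.  The largest
    4-connected component of passing pixels is returned as a boolean mask.

    Raises
    ------
    WindowNotFoundError
        If no component covers at least ``min_area_fraction`` of the image.
        Callers may fall back to an explicit rectangle ROI
        (:func:`rectangle_mask`).
    """
    if not 0.0 <= min_saturation <= 100.0:
        raise ValueError("min_saturation must lie in [0, 100]")
    if not 0.0 < min_area_fraction < 1.0:
        raise ValueError("min_area_fraction must lie in (0, 1)")
    arr = np.asarray(image)
    hsb = rgb_to_hsb(arr)
    passing = _hue_in_range(hsb[..., 0], hue_range) & (hsb[..., 1] >= min_saturation)

    labels, n_components = ndimage.label(passing, structure=_STRUCTURE_4)
    if n_components == 0:
        raise WindowNotFoundError("no pixels pass the hue/saturation threshold")
    sizes = ndimage.sum_labels(passing, labels, index=np.arange(1, n_components + 1))
    best = int(np.argmax(sizes)) + 1
    area = int(sizes[best - 1])
    if area < min_area_fraction * arr.shape[0] * arr.shape[1]:
        raise WindowNotFoundError(
            f"largest colored component ({area} px) is below "
            f"{min_area_fraction:.0%} of the image area"
        )
    return labels == best


def rectangle_mask(
    shape: tuple[int, int], x: int, y: int, width: int, height: int
) -> np.ndarray:
    """Boolean mask for an axis-aligned rectangle (explicit-ROI fallback)."""
    rows, cols = shape[:2]
    if width < 1 or height < 1:
        raise ValueError("rectangle must have positive size")
    if x < 0 or y < 0 or x + width > cols or y + height > rows:
        raise ValueError("rectangle outside image bounds")
    mask = np.zeros((rows, cols), dtype=bool)
    mask[y : y + height, x : x + width] = True
    return mask
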
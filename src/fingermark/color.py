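"""Color-space measurement of assay detection windows.

The Sakaguchi reaction yields a red complex whose color intensity tracks
arginine concentration.  The quantitative readout used throughout this
package is the mean HSB saturation of the detection-window pixels after a
red-to-magenta channel substitution ("tinting"): the blue channel is
replaced by a copy of the red channel, which boosts the red channel's
contribution and linearizes the saturation response.  Mean red-channel
intensity is also computed (always on the untinted image) because it is the
naive metric one would try first; it correlates poorly with concentration
and is kept only for diagnostics.

All images are 8-bit RGB arrays of shape (height, width, 3).  Saturation is
reported on the conventional 0-100 % scale with S = 100*(max-min)/max over
the three channels (S = 0 for black), brightness as 100*max/255, hue in
degrees [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColorMetrics", "red_to_magenta", "rgb_to_hsb", "measure"]


@dataclass(frozen=True)
class ColorMetrics:
    """Summary color statistics over a pixel mask.

    Attributes
    ----------
    mean_red : float
        Mean of the untinted red channel, 0-255 units.
    mean_saturation : float
        Mean per-pixel HSB saturation, percent (0-100).
    pixel_count : int
        Number of pixels the means were taken over.
    """

    mean_red: float
    mean_saturation: float
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")
        if not 0.0 <= self.mean_red <= 255.0:
            raise ValueError("mean_red outside [0, 255]")
        if not 0.0 <= self.mean_saturation <= 100.0:
            raise ValueError("mean_saturation outside [0, 100]")


def _as_rgb_array(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    return arr


def red_to_magenta(image: np.ndarray) -> np.ndarray:
    """Replace the blue channel with a copy of the red channel.

    Turns pure red into magenta while leaving red and green untouched.
    Idempotent: applying it twice equals applying it once.
    """
    arr = _as_rgb_array(image)
    out = arr.copy()
    out[..., 2] = out[..., 0]
    return out


def rgb_to_hsb(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB values to HSB (hue deg, saturation %, brightness %).

    Accepts a single pixel ``(r, g, b)`` or any array whose last axis has
    length 3.  Computation is in floating point; no 8-bit re-quantization of
    the saturation image is performed.

    Hue follows the standard hexagonal formula; saturation of black pixels
    (max = 0) is 0 by convention.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must have length 3 (R, G, B)")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = mx - mn

    safe_mx = np.where(mx > 0, mx, 1.0)
    sat = np.where(mx > 0, 100.0 * delta / safe_mx, 0.0)
    bri = 100.0 * mx / 255.0

    safe_delta = np.where(delta > 0, delta, 1.0)
    hue = np.select(
        [delta == 0, mx == r, mx == g],
        [
            0.0,
            (60.0 * ((g - b) / safe_delta)) % 360.0,
            60.0 * ((b - r) / safe_delta) + 120.0,
        ],
        default=60.0 * ((r - g) / safe_delta) + 240.0,
    )
    return np.stack([hue, sat, bri], axis=-1)


def measure(image: np.ndarray, mask: np.ndarray, tint: bool = True) -> ColorMetrics:
    """Measure mean red and mean saturation of ``image`` over ``mask``.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3)
        8-bit RGB image.
    mask : ndarray of bool, shape (H, W)
        Region of interest; must select at least one pixel.
    tint : bool, default True
        Apply the red-to-magenta substitution before computing saturation.
        This is the standard measurement protocol; ``mean_red`` is always
        taken from the untinted image regardless.

    Returns
    -------
    ColorMetrics
    """
    arr = _as_rgb_array(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {arr.shape[:2]}"
        )
    count = int(mask.sum())
    if count < 1:
        raise ValueError("empty mask")

    pixels = arr[mask].astype(np.float64)
    mean_red = float(pixels[:, 0].mean())

    working = red_to_magenta(arr) if tint else arr
    sats = rgb_to_hsb(working[mask])[:, 1]
    return ColorMetrics(
        mean_red=mean_red,
        mean_saturation=float(sats.mean()),
        pixel_count=count,
    )
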
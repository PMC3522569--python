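"""RGB to HSI / YCbCr / YIQ conversions used by the color feature extractor.

All arithmetic is carried out on [0, 1] normalized reals.  8-bit integer
input is divided by 255 on entry.  Conventions:

* HSI: I = (R+G+B)/3; S = 1 - min/mean (0 at black); H from the standard
  geometric (arccos) formula, divided by 360 so that H lies in [0, 1].
* YCbCr: BT.601 full-range (the JPEG convention); Cb and Cr are centered
  at 0.5 on the normalized scale.
* YIQ: the NTSC/FCC matrix; I and Q are signed.

Singularities are defined deterministically: S = 0 at black, H = 0 at any
achromatic pixel, so all twelve planes are finite for every valid input.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

#: Canonical plane order for the 24 color features (mean, variance per plane).
PLANE_NAMES = (
    "R", "G", "B",
    "H", "I_hsi", "S",
    "Y_cbcr", "Cb", "Cr",
    "Y_yiq", "I_yiq", "Q",
)

# BT.601 luma weights, shared by YCbCr and YIQ.
_LUMA = np.array([0.299, 0.587, 0.114])

_YIQ_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.595716, -0.274453, -0.321263],
        [0.211456, -0.522591, 0.311135],
    ]
)

_YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)


def as_float_rgb(img: np.ndarray) -> np.ndarray:
    """Validate an RGB raster and return it as float64 in [0, 1].

    Accepts H x W x 3 arrays, either integer in [0, 255] or real in [0, 1].
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise FormatError("image must contain at least one pixel")
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 255:
            raise FormatError("integer RGB values must lie in [0, 255]")
        return np.ascontiguousarray(arr, dtype=np.float64) / 255.0
    # enforce C order so reductions are bit-reproducible across storage layouts
    arr = np.ascontiguousarray(arr, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise FormatError("RGB values must be finite")
    if arr.min() < 0.0 or arr.max() > 1.0 + 1e-9:
        raise FormatError("real RGB values must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0)


def rgb_to_hsi(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the (H, S, I) planes; all three rescaled into [0, 1].

    Hue is computed in degrees by the geometric formula and divided by 360.
    """
    rgb = as_float_rgb(img)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / 3.0

    minimum = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(total > 0.0, 1.0 - 3.0 * minimum / np.where(total > 0, total, 1.0), 0.0)
    sat = np.clip(sat, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = den < 1e-12
    cos_t = np.where(achromatic, 1.0, num / np.where(achromatic, 1.0, den))
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(achromatic, 0.0, hue) / 360.0
    return hue, sat, intensity


def rgb_to_ycbcr(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Y, Cb, Cr) by the BT.601 full-range transform on [0, 1] reals.

    Cb and Cr are centered at 0.5 (i.e. 128 on the 8-bit scale).
    """
    rgb = as_float_rgb(img)
    out = rgb @ _YCBCR_MATRIX.T
    return out[..., 0], out[..., 1] + 0.5, out[..., 2] + 0.5


def rgb_to_yiq(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Y, I, Q) by the NTSC matrix; I and Q are signed."""
    rgb = as_float_rgb(img)
    out = rgb @ _YIQ_MATRIX.T
    return out[..., 0], out[..., 1], out[..., 2]


def color_planes(img: np.ndarray) -> dict[str, np.ndarray]:
    """All 12 named component planes of an RGB image, in canonical order.

    The four color spaces share R, G, B as input; the duplicated Y and I
    symbols of the HSI/YCbCr/YIQ union are disambiguated as
    (I_hsi, I_yiq) and (Y_cbcr, Y_yiq).
    """
    rgb = as_float_rgb(img)
    h, s, i_hsi = rgb_to_hsi(rgb)
    y_cbcr, cb, cr = rgb_to_ycbcr(rgb)
    y_yiq, i_yiq, q = rgb_to_yiq(rgb)
    planes = {
        "R": rgb[..., 0],
        "G": rgb[..., 1],
        "B": rgb[..., 2],
        "H": h,
        "I_hsi": i_hsi,
        "S": s,
        "Y_cbcr": y_cbcr,
        "Cb": cb,
        "Cr": cr,
        "Y_yiq": y_yiq,
        "I_yiq": i_yiq,
        "Q": q,
    }
    assert tuple(planes) == PLANE_NAMES
    return planes


def luminance(img: np.ndarray) -> np.ndarray:
    """BT.601 luma plane in [0, 1]; the gray image for texture and moments."""
    return as_float_rgb(img) @ _LUMA
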
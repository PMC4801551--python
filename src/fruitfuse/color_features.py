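"""Chromatic feature extraction for ripeness segmentation.

Mature (red) fruit is separated from green canopy material using two
chrominance channels that respond strongly to the red-green axis:

* the a* component of CIE L*a*b*, computed from *chromaticity* coordinates
  r = R/(R+G+B) etc., which makes it independent of overall intensity; and
* the I (in-phase) component of NTSC YIQ, a linear combination of the raw
  8-bit channels spanning the orange-cyan axis.

The L*a*b* chain goes RGB -> chromaticity -> XYZ (fixed 3x3 matrix whose
rows each sum to 1, so gray inputs land on X = Y = Z) -> L*a*b* via the
standard piecewise cube-root companding function f(t).

All arithmetic is double precision; quantization to 8 bits happens only at
file output, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RGB_TO_XYZ",
    "RGB_TO_YIQ",
    "FeatureImage",
    "rgb_normalize",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_yiq",
    "extract_feature_images",
    "normalize_feature",
]

# Chromaticity -> XYZ. Each row sums to 1.000000, so r=g=b implies X=Y=Z
# and hence a* = b* = 0 for any gray pixel.
RGB_TO_XYZ = np.array(
    [
        [0.433953, 0.376219, 0.189828],
        [0.212671, 0.715160, 0.072169],
        [0.017758, 0.109477, 0.872765],
    ]
)

# Raw 8-bit RGB -> YIQ (NTSC). Rows: Y (luma), I (orange-cyan), Q.
RGB_TO_YIQ = np.array(
    [
        [0.2990, 0.5870, 0.1140],
        [0.5957, -0.2745, -0.3213],
        [0.2115, -0.5226, 0.3111],
    ]
)

# Piecewise companding f(t): cube root above the breakpoint, linear below.
LAB_BREAKPOINT = 0.008856
LAB_SLOPE = 7.787
LAB_OFFSET = 16.0 / 116.0


def _validate_rgb(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB data with a trailing axis of size 3")
    if not np.all(np.isfinite(arr)):
        raise ValueError("RGB channels must be finite")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    return arr


def rgb_normalize(pixels) -> np.ndarray:
    """Chromaticity coordinates r = R/(R+G+B), g, b for one pixel or an array.

    A black pixel has no defined chromaticity; it is mapped to the gray point
    (1/3, 1/3, 1/3), which is the limit of dark grays and keeps the
    conversion total on real scenes.
    """
    arr = _validate_rgb(pixels)
    total = arr.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = np.where(total > 0, arr / np.where(total > 0, total, 1.0), 1.0 / 3.0)
    return chroma


def rgb_to_xyz(chroma) -> np.ndarray:
    """XYZ triple(s) from chromaticity coordinates (fixed-matrix product)."""
    arr = np.asarray(chroma, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("expected chromaticity data with a trailing axis of size 3")
    return arr @ RGB_TO_XYZ.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    return np.where(t > LAB_BREAKPOINT, np.cbrt(t), LAB_SLOPE * t + LAB_OFFSET)


def xyz_to_lab(xyz) -> np.ndarray:
    """(L*, a*, b*) from XYZ.

    L* = 116 f(Y) - 16, a* = 500 (f(X) - f(Y)), b* = 200 (f(Y) - f(Z)).
    Negative tristimulus values are rejected: the cube-root branch is not
    defined for them and they cannot arise from non-negative chromaticities.
    """
    arr = np.asarray(xyz, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("expected XYZ data with a trailing axis of size 3")
    if not np.all(np.isfinite(arr)):
        raise ValueError("XYZ values must be finite")
    if arr.min() < 0:
        raise ValueError("XYZ values must be non-negative")
    f = _lab_f(arr)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    lab = np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)
    return lab


def rgb_to_yiq(pixels) -> np.ndarray:
    """(Y, I, Q) from raw 8-bit RGB channels (linear NTSC matrix)."""
    arr = _validate_rgb(pixels)
    return arr @ RGB_TO_YIQ.T


@dataclass
class FeatureImage:
    """One chromatic feature of an RGB image.

    ``values`` holds the raw feature (a* or I) at full precision;
    ``normalized`` is its min-max rescale to [0, 1], populated by
    :func:`normalize_feature` and consumed by the fusion stage.
    """

    values: np.ndarray
    channel_tag: str  # "a_star" or "I"
    normalized: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def extract_feature_images(img) -> tuple[FeatureImage, FeatureImage]:
    """Compute the a*-component and I-component images of an RGB image.

    The a* chain uses chromaticity coordinates (intensity-invariant); the I
    chain uses the raw channels. Output grids match the input height/width.
    """
    arr = _validate_rgb(img)
    if arr.ndim != 3:
        raise ValueError("expected an H x W x 3 image")
    if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.size == 0:
        raise ValueError("image must have at least one pixel")
    lab = xyz_to_lab(rgb_to_xyz(rgb_normalize(arr)))
    yiq = rgb_to_yiq(arr)
    return (
        FeatureImage(values=lab[..., 1], channel_tag="a_star"),
        FeatureImage(values=yiq[..., 1], channel_tag="I"),
    )


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant grid maps to all zeros."""
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature values must be finite")
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def normalize_feature(f: FeatureImage) -> FeatureImage:
    """Return a copy of ``f`` with the ``normalized`` grid populated.

    Normalization bounds the fusion-weight computation: the weight is the
    dynamic range of the elementwise max of the two features, which is only
    a convex mixing proportion if both inputs live in [0, 1].
    """
    return FeatureImage(
        values=f.values,
        channel_tag=f.channel_tag,
        normalized=minmax_normalize(f.values),
    )
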
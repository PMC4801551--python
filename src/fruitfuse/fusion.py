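"""Pixel-level fusion of the two feature images in the wavelet domain.

Both normalized feature images are decomposed with a multilevel 2-D discrete
wavelet transform, every coefficient subband is blended with one convex
weight, and the blend is reconstructed:

    C = (1 - d) * C1 + d * C2

The weight d is the dynamic range (max - min) of the elementwise maximum of
the two normalized source images. Because a single scalar applied to every
coefficient of a linear, perfectly invertible transform commutes with
reconstruction, the fused image equals the pixelwise mixture
(1 - d) * A + d * B up to boundary round-off; this identity is the module's
main internal consistency check. A per-subband weight variant (one d per
coefficient array, computed from the coefficient pair itself) is available
for users who want the decomposition to matter, but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .color_features import FeatureImage

__all__ = [
    "DEFAULT_WAVELET",
    "DEFAULT_LEVELS",
    "FusionWeight",
    "WaveletCoeffs",
    "compute_fusion_weight",
    "wavelet_decompose",
    "wavelet_reconstruct",
    "fuse_coefficients",
    "fuse_images",
    "simple_fusion_baseline",
]

DEFAULT_WAVELET = "db2"
DEFAULT_LEVELS = 3
_BOUNDARY_MODE = "symmetric"  # avoids edge artifacts in reconstruction


def _as_grid(img) -> np.ndarray:
    if isinstance(img, FeatureImage):
        if img.normalized is None:
            raise ValueError("FeatureImage must be normalized before fusion")
        return np.asarray(img.normalized, dtype=np.float64)
    return np.asarray(img, dtype=np.float64)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass
class FusionWeight:
    """Range-based mixing proportion d = x_max - x_min of the max image."""

    d: float
    x_min: float
    x_max: float


@dataclass
class WaveletCoeffs:
    """Multilevel 2-D DWT of a feature image.

    ``details`` is ordered coarse-to-fine, each entry a
    (horizontal, vertical, diagonal) triple of subband grids.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    levels: int
    wavelet_name: str = DEFAULT_WAVELET
    shape: tuple[int, int] | None = None

    def _to_pywt(self):
        return [self.approximation] + [list(d) for d in self.details]


def compute_fusion_weight(a, b) -> FusionWeight:
    """Weight d from two same-shape normalized images.

    The elementwise maximum L_max of the pair is formed and d is its dynamic
    range. d is bounded by [0, 1] for inputs in [0, 1], and is symmetric in
    the argument order because the elementwise max is.
    """
    a = _as_grid(a)
    b = _as_grid(b)
    _check_pair(a, b)
    l_max = np.maximum(a, b)
    x_min = float(l_max.min())
    x_max = float(l_max.max())
    return FusionWeight(d=x_max - x_min, x_min=x_min, x_max=x_max)


def wavelet_decompose(
    img, levels: int = DEFAULT_LEVELS, wavelet_name: str = DEFAULT_WAVELET
) -> WaveletCoeffs:
    """Multilevel 2-D DWT with symmetric boundary extension."""
    arr = _as_grid(img)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    min_size = 2**levels
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(
            f"image of shape {arr.shape} too small for {levels} levels; "
            f"each dimension must be >= {min_size}"
        )
    coeffs = pywt.wavedec2(arr, wavelet_name, mode=_BOUNDARY_MODE, level=levels)
    return WaveletCoeffs(
        approximation=coeffs[0],
        details=[tuple(d) for d in coeffs[1:]],
        levels=levels,
        wavelet_name=wavelet_name,
        shape=arr.shape,
    )


def wavelet_reconstruct(coeffs: WaveletCoeffs) -> np.ndarray:
    """Inverse transform; cropped back to the source shape if recorded."""
    out = pywt.waverec2(coeffs._to_pywt(), coeffs.wavelet_name, mode=_BOUNDARY_MODE)
    if coeffs.shape is not None:
        out = out[: coeffs.shape[0], : coeffs.shape[1]]
    return out


def _structure_matches(c1: WaveletCoeffs, c2: WaveletCoeffs) -> bool:
    if c1.levels != c2.levels or c1.wavelet_name != c2.wavelet_name:
        return False
    if c1.approximation.shape != c2.approximation.shape:
        return False
    return all(
        g1.shape == g2.shape
        for d1, d2 in zip(c1.details, c2.details)
        for g1, g2 in zip(d1, d2)
    )


def _subband_weight(g1: np.ndarray, g2: np.ndarray) -> float:
    l_max = np.maximum(g1, g2)
    d = float(l_max.max() - l_max.min())
    return min(max(d, 0.0), 1.0)  # coefficients are unbounded; clamp


def fuse_coefficients(
    c1: WaveletCoeffs,
    c2: WaveletCoeffs,
    weight: FusionWeight | None = None,
    per_subband: bool = False,
) -> WaveletCoeffs:
    """Convex blend (1-d)*C1 + d*C2 of every subband.

    With ``per_subband`` a separate d is computed from each coefficient pair
    by the same range rule (clamped to [0, 1]); otherwise the single global
    ``weight`` is applied to approximation and all detail subbands alike.
    """
    if not _structure_matches(c1, c2):
        raise ValueError("coefficient structures do not match")
    if not per_subband and weight is None:
        raise ValueError("a global FusionWeight is required unless per_subband=True")

    def blend(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        d = _subband_weight(g1, g2) if per_subband else weight.d
        return (1.0 - d) * g1 + d * g2

    return WaveletCoeffs(
        approximation=blend(c1.approximation, c2.approximation),
        details=[
            tuple(blend(g1, g2) for g1, g2 in zip(d1, d2))
            for d1, d2 in zip(c1.details, c2.details)
        ],
        levels=c1.levels,
        wavelet_name=c1.wavelet_name,
        shape=c1.shape,
    )


def fuse_images(
    a,
    b,
    levels: int = DEFAULT_LEVELS,
    wavelet_name: str = DEFAULT_WAVELET,
    per_subband_weight: bool = False,
) -> np.ndarray:
    """Full fusion path: weight, decompose, blend, reconstruct, clip.

    Inputs are normalized feature images (values in [0, 1], same shape).
    The output is clipped to [0, 1] so the downstream 8-bit gray mapping
    stays bounded.
    """
    a = _as_grid(a)
    b = _as_grid(b)
    _check_pair(a, b)
    weight = compute_fusion_weight(a, b)
    c1 = wavelet_decompose(a, levels=levels, wavelet_name=wavelet_name)
    c2 = wavelet_decompose(b, levels=levels, wavelet_name=wavelet_name)
    fused = fuse_coefficients(c1, c2, weight=weight, per_subband=per_subband_weight)
    out = wavelet_reconstruct(fused)
    return np.clip(out, 0.0, 1.0)


def simple_fusion_baseline(a, b) -> np.ndarray:
    """Direct pixelwise combination (arithmetic mean) of the two features."""
    a = _as_grid(a)
    b = _as_grid(b)
    _check_pair(a, b)
    return 0.5 * (a + b)
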
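"""Adaptive threshold segmentation of the fused gray image.

Two global thresholds are computed on the 8-bit gray scale and the smaller
one wins:

* an iterative (ISODATA-style) threshold: start at the midpoint of the gray
  extremes, split the image into the classes above/below, move the threshold
  to the mean of the two class means, repeat to a fixed point;
* Otsu's threshold: the gray level maximizing between-class variance, found
  by exhaustive search over the 256 candidate levels with ties broken by the
  lowest maximizing level (deterministic and pixel-order independent).

Binarization follows the <=-threshold convention for the ``low`` polarity;
the default polarity is ``high`` (foreground = values strictly above the
threshold), which is the orientation in which mature fruit — bright in the
fused feature image — becomes foreground.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_TOLERANCE",
    "ThresholdReport",
    "iterative_threshold",
    "otsu_threshold",
    "final_threshold",
    "binarize",
    "threshold_report",
]

# Convergence tolerance on the 8-bit gray scale. Sub-quantization precision
# is meaningless for an 8-bit threshold, and exact float equality is fragile.
DEFAULT_TOLERANCE = 0.5
_MAX_ITERATIONS = 256


def _as_gray(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("image must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("gray values must be finite")
    return arr


@dataclass
class ThresholdReport:
    """The three thresholds and the iteration trace that produced T_m."""

    t_m: float
    t_n: float
    t_f: float
    iterations: list[float]
    t_max: float
    t_min: float
    t_a: float  # final mean of the above-threshold class
    t_b: float  # final mean of the below-or-equal class
    w: int  # pixels strictly above the final iterative threshold
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "t_m": self.t_m,
            "t_n": self.t_n,
            "t_f": self.t_f,
            "iterations": list(self.iterations),
            "t_max": self.t_max,
            "t_min": self.t_min,
            "t_a": self.t_a,
            "t_b": self.t_b,
            "w": self.w,
            "degenerate": self.degenerate,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def iterative_threshold(
    img, tolerance: float = DEFAULT_TOLERANCE, max_iterations: int = _MAX_ITERATIONS
) -> tuple[float, list[float]]:
    """Fixed-point class-mean threshold; returns (T_m, iteration trace).

    T^0 = (T_max + T_min) / 2. At each step the image splits into A
    (values > T^k) and B (values <= T^k; ties go to B, matching the
    <=-threshold binarization convention) and T^{k+1} = (mean_A + mean_B)/2.
    Iteration stops when |T^{k+1} - T^k| < ``tolerance``. A constant image
    is degenerate and returns the constant with a single-entry trace.
    """
    arr = _as_gray(img)
    t_max = float(arr.max())
    t_min = float(arr.min())
    t = (t_max + t_min) / 2.0
    trace = [t]
    if t_max == t_min:
        return t, trace
    for _ in range(max_iterations):
        above = arr > t
        mean_a = float(arr[above].mean())
        mean_b = float(arr[~above].mean())
        t_next = (mean_a + mean_b) / 2.0
        trace.append(t_next)
        if abs(t_next - t) < tolerance:
            return t_next, trace
        t = t_next
    return t, trace


def otsu_threshold(img) -> float:
    """Between-class-variance-maximizing gray level on a 256-bin histogram.

    The image is expected on the 0-255 scale (it is rounded to integer bins
    internally). All 256 candidate levels t are scored with the class split
    (<= t, > t); the lowest maximizing level is returned. A constant image
    returns the constant itself.
    """
    arr = _as_gray(img)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("Otsu search expects gray values in [0, 255]")
    if arr.max() == arr.min():
        return float(arr.flat[0])
    hist = np.bincount(np.round(arr).astype(np.int64).ravel(), minlength=256).astype(
        np.float64
    )
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    cum_n = np.cumsum(hist)  # pixels <= t
    cum_sum = np.cumsum(hist * levels)
    mean_total = cum_sum[-1] / total
    w0 = cum_n / total
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(cum_n > 0, cum_sum / cum_n, 0.0)
        mu1 = np.where(
            cum_n < total, (cum_sum[-1] - cum_sum) / (total - cum_n), 0.0
        )
    variance = w0 * w1 * (mu0 - mu1) ** 2
    variance[~np.isfinite(variance)] = 0.0
    return float(np.argmax(variance))  # argmax returns the lowest maximizer


def final_threshold(t_m: float, t_n: float) -> float:
    """Combine the two thresholds: the smaller one is final."""
    if not (np.isfinite(t_m) and np.isfinite(t_n)):
        raise ValueError("thresholds must be finite")
    return float(t_n) if t_m >= t_n else float(t_m)


def binarize(img, t_f: float, polarity: str = "high") -> np.ndarray:
    """Binary mask from a gray image and final threshold.

    ``polarity='low'`` marks values <= T_f as foreground (the literal
    binarization rule); ``polarity='high'`` (default) marks values > T_f,
    the orientation in which bright fused-image fruit is foreground.
    """
    arr = _as_gray(img)
    if not np.isfinite(t_f):
        raise ValueError("threshold must be finite")
    if polarity == "low":
        mask = arr <= t_f
    elif polarity == "high":
        mask = arr > t_f
    else:
        raise ValueError(f"unknown polarity {polarity!r}; expected 'high' or 'low'")
    return mask.astype(np.uint8)


def threshold_report(img, tolerance: float = DEFAULT_TOLERANCE) -> ThresholdReport:
    """Run both threshold estimators and the min-combination rule."""
    arr = _as_gray(img)
    t_max = float(arr.max())
    t_min = float(arr.min())
    degenerate = t_max == t_min
    t_m, trace = iterative_threshold(arr, tolerance=tolerance)
    t_n = otsu_threshold(arr)
    t_f = final_threshold(t_m, t_n)
    above = arr > t_m
    w = int(above.sum())
    t_a = float(arr[above].mean()) if w else t_m
    t_b = float(arr[~above].mean()) if w < arr.size else t_m
    return ThresholdReport(
        t_m=t_m,
        t_n=t_n,
        t_f=t_f,
        iterations=trace,
        t_max=t_max,
        t_min=t_min,
        t_a=t_a,
        t_b=t_b,
        w=w,
        degenerate=degenerate,
    )
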
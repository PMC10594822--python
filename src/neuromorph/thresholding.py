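"""Global histogram thresholding.

Six standard methods are provided: ``otsu`` (default), ``mean``, ``isodata``,
``triangle``, ``li`` and ``yen``. Object polarity is always explicit —
phase-contrast somata may appear dark with bright halos, so no default
polarity is assumed anywhere.

Conventions, pinned for determinism:

* ``bright`` foreground is strictly ``intensity > T``; ``dark`` is the exact
  complement ``intensity <= T``.
* Otsu and isodata work on the native histogram (256 bins for 8-bit, 65 536
  for 16-bit), never on a rescaled one.
* Otsu is computed in exact integer arithmetic, so the returned threshold is
  the true argmax of the between-class variance with ties broken toward the
  lowest qualifying intensity — never a floating-point near-miss.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters as _skfilters

from .errors import DegenerateImageError, ValidationError
from .image import GrayImage

__all__ = ["ThresholdMethod", "compute_threshold", "binarize", "segment", "METHODS"]

METHODS = ("otsu", "mean", "isodata", "triangle", "li", "yen")
POLARITIES = ("dark", "bright")


@dataclass(frozen=True)
class ThresholdMethod:
    """A named global thresholding algorithm plus the object polarity."""

    name: str = "otsu"
    object_polarity: str = "bright"

    def __post_init__(self) -> None:
        if self.name not in METHODS:
            raise ValidationError(f"unknown threshold method {self.name!r}; choose from {METHODS}")
        if self.object_polarity not in POLARITIES:
            raise ValidationError(
                f"object_polarity must be 'dark' or 'bright', got {self.object_polarity!r}"
            )


def _histogram(image: GrayImage) -> np.ndarray:
    return np.bincount(image.pixels.ravel(), minlength=image.max_value + 1)


def _otsu_exact(hist: np.ndarray) -> int:
    """Exact-arithmetic Otsu threshold.

    Maximizes the between-class variance
    ``sigma_b^2(T) = w0 w1 (mu0 - mu1)^2`` with class 0 = intensities <= T.
    Up to normalization this equals ``(S0*N - S*N0)^2 / (N0*(N-N0))`` with
    integer ``N0`` (count <= T), ``S0`` (intensity sum <= T); fractions are
    compared by cross-multiplication of Python ints, so results are exact and
    ties resolve to the lowest T.
    """
    counts = [int(c) for c in hist]
    n_total = sum(counts)
    s_total = sum(v * c for v, c in enumerate(counts))
    best_t, best_num, best_den = -1, -1, 1
    n0 = 0
    s0 = 0
    for t, c in enumerate(counts):
        n0 += c
        s0 += t * c
        n1 = n_total - n0
        if n0 == 0 or n1 == 0:
            continue
        num = (s0 * n_total - s_total * n0) ** 2
        den = n0 * n1
        # num/den > best_num/best_den  <=>  num*best_den > best_num*den
        if num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    if best_t < 0:
        raise DegenerateImageError("constant image: between-class variance undefined")
    return best_t


def _isodata_iterative(image: GrayImage) -> float:
    """Ridler–Calvard fixed point: T = (mean(<=T) + mean(>T)) / 2."""
    px = image.pixels.ravel().astype(np.float64)
    t = float(px.mean())
    for _ in range(500):
        below = px[px <= t]
        above = px[px > t]
        if below.size == 0 or above.size == 0:
            # nudge into the open interval between the extremes
            t = (float(px.min()) + float(px.max())) / 2.0
            below = px[px <= t]
            above = px[px > t]
        t_next = (below.mean() + above.mean()) / 2.0
        if abs(t_next - t) < 0.5:
            return t_next
        t = t_next
    return t


def compute_threshold(image: GrayImage, method: ThresholdMethod | str = "otsu") -> float:
    """Compute a global threshold T in intensity units.

    The returned T always leaves both classes non-empty: ``min <= T < max``
    over the image's intensities, so a ``bright`` foreground (``> T``) is
    never the whole image and never empty.

    Raises
    ------
    DegenerateImageError
        If the image is constant (fewer than two distinct intensities).
    """
    if isinstance(method, str):
        method = ThresholdMethod(name=method)
    px = image.pixels
    lo, hi = int(px.min()), int(px.max())
    if lo == hi:
        raise DegenerateImageError(
            f"cannot threshold a constant image (single intensity {lo})"
        )
    name = method.name
    if name == "otsu":
        t: float = float(_otsu_exact(_histogram(image)))
    elif name == "mean":
        t = float(px.mean())
    elif name == "isodata":
        t = float(_isodata_iterative(image))
    elif name == "triangle":
        t = float(_skfilters.threshold_triangle(image.astype_native(), nbins=image.max_value + 1))
    elif name == "li":
        t = float(_skfilters.threshold_li(image.astype_native()))
    else:  # yen
        t = float(_skfilters.threshold_yen(image.astype_native(), nbins=image.max_value + 1))
    # keep both classes non-empty under '> T': need lo <= T < hi
    if t < lo:
        t = float(lo)
    elif t >= hi:
        t = float(np.max(px[px < hi]))  # largest intensity below the maximum
    return float(t)


def binarize(image: GrayImage, t: float, polarity: str = "bright") -> np.ndarray:
    """Binarize at threshold ``t``: bright -> ``> t``, dark -> ``<= t``."""
    if polarity not in POLARITIES:
        raise ValidationError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    bright = image.pixels > t
    return bright if polarity == "bright" else ~bright


def segment(image: GrayImage, method: ThresholdMethod | str = "otsu") -> np.ndarray:
    """Threshold and binarize in one step, honoring the method's polarity."""
    if isinstance(method, str):
        method = ThresholdMethod(name=method)
    t = compute_threshold(image, method)
    return binarize(image, t, method.object_polarity)
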
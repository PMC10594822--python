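"""Core raster container for 2D grayscale microscopy frames.

A :class:`GrayImage` wraps an integer pixel grid together with its bit depth
and an optional physical pixel size. Binary masks and label maps are plain
``numpy`` arrays (``bool`` and ``int`` respectively) throughout the package;
only the raw intensity image carries metadata worth a container.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["GrayImage"]


@dataclass(frozen=True)
class GrayImage:
    """A single-plane grayscale image.

    Parameters
    ----------
    pixels
        2D array of non-negative integers (any integer dtype).
    bit_depth
        8 or 16; all pixel values must fit in this depth.
    pixel_size_um
        Optional physical scale, micrometres per pixel (> 0 when given).
        Purely informational: all measurements in this package are reported
        in pixel units.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"image must be 2D and non-empty, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError(f"image dtype must be integer, got {px.dtype}")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValidationError(
                f"pixel values [{px.min()}, {px.max()}] outside {self.bit_depth}-bit range"
            )
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0 when present")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        """Largest representable intensity at this bit depth."""
        return (1 << self.bit_depth) - 1

    def astype_native(self) -> np.ndarray:
        """Pixels as the natural unsigned dtype for the bit depth."""
        return self.pixels.astype(np.uint8 if self.bit_depth == 8 else np.uint16)
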
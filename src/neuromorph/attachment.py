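"""Neurite attachment-point detection.

Attachment points — a collective term for neurite trunks and terminal ends —
are the loci where neurite outlines meet cell-body outlines. The operator:

1. take 1-px inner outlines of the cell-body and neurite objects,
2. run a 3×3 Sobel pair over the neurite outlines and keep every pixel with
   nonzero gradient magnitude (the edge band hugging the outline),
3. dilate both operands by ``dilation_px`` (8-connected, default 1) — a soma
   boundary and a neurite edge can be 8-adjacent without sharing a pixel,
4. intersect them pixelwise (the binary equivalent of inverting 0/255 images
   and multiplying), and
5. count 8-connected components of the overlap: one component = one
   attachment point.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError

__all__ = ["AttachmentPointSet", "outline", "sobel_edges", "detect_attachment_points"]

_STRUCT_8 = np.ones((3, 3), bool)

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.int64)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class AttachmentPointSet:
    """Detected neurite↔cell-body contact loci for one image."""

    overlap_mask: np.ndarray
    points: list[dict] = field(default_factory=list)  # {centroid: (row,col), area: px²}
    count: int = 0


def outline(labels_or_mask: np.ndarray) -> np.ndarray:
    """1-px inner boundary: object pixels with ≥1 background 8-neighbor.

    Pixels on the image border always count as boundary (outside the frame
    is background).
    """
    mask = np.asarray(labels_or_mask) != 0
    interior = ndi.binary_erosion(mask, structure=_STRUCT_8, border_value=0)
    return mask & ~interior


def sobel_edges(mask: np.ndarray) -> np.ndarray:
    """Nonzero-gradient pixels of the 3×3 Sobel pair on a 0/1 mask.

    Integer convolution, so "nonzero" is exact; a constant mask gives an
    empty result.
    """
    m = np.asarray(mask, bool).astype(np.int64)
    gx = ndi.convolve(m, _SOBEL_X, mode="constant", cval=0)
    gy = ndi.convolve(m, _SOBEL_Y, mode="constant", cval=0)
    return (gx != 0) | (gy != 0)


def _dilate(mask: np.ndarray, px: int) -> np.ndarray:
    if px == 0:
        return mask
    return ndi.binary_dilation(mask, structure=_STRUCT_8, iterations=px)


def detect_attachment_points(
    cell_body_outlines: np.ndarray,
    neurite_outlines: np.ndarray,
    dilation_px: int = 1,
) -> AttachmentPointSet:
    """Overlap cell-body outlines with the Sobel band of neurite outlines.

    Parameters
    ----------
    dilation_px
        8-connected dilation applied to both operands before the
        intersection; 0 requires genuinely shared pixels.
    """
    cb = np.asarray(cell_body_outlines, bool)
    nr = np.asarray(neurite_outlines, bool)
    if cb.shape != nr.shape:
        raise ValidationError(f"shape mismatch: {cb.shape} vs {nr.shape}")
    if dilation_px < 0:
        raise ValidationError("dilation_px must be >= 0")
    edges = sobel_edges(nr)
    overlap = _dilate(cb, dilation_px) & _dilate(edges, dilation_px)
    labels, n = ndi.label(overlap, structure=_STRUCT_8)
    points = []
    if n:
        centroids = ndi.center_of_mass(overlap, labels, range(1, n + 1))
        areas = ndi.sum_labels(overlap, labels, range(1, n + 1))
        points = [
            {"centroid": (float(r), float(c)), "area": float(a)}
            for (r, c), a in zip(centroids, areas)
        ]
    return AttachmentPointSet(overlap_mask=overlap, points=points, count=int(n))
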
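"""Per-object shape descriptors and cell-body / neurite classification.

Every labeled object ("motif") gets one :class:`MotifRecord` with:

``area``
    pixel count.
``perimeter``
    length of the closed chain through the centers of the outer boundary
    pixels (Moore-neighbor trace), axis steps weighted 1 and diagonal steps
    weighted √2; a 10×10 square measures exactly 36. Single pixels are 4 by
    convention.
``circularity``
    ``4π·area / perimeter²``, capped at 1.0.
``major_axis`` / ``minor_axis`` / ``aspect_ratio``
    lengths of the moments-equivalent ellipse axes (rotation invariant);
    each axis is floored at 1 px — a one-pixel-wide bar is physically one
    pixel wide, not zero — so the ratio is always finite and ≥ 1.
``length``
    maximum Feret diameter: the largest distance between boundary-pixel
    centers (default), or the longest geodesic through the morphological
    skeleton (``length_method="skeleton"``, better for curved neurites).

Classification is a pure filter over these descriptors: a cell-body pass
admits objects inside the per-cell-type area and circularity windows, a
neurite pass additionally requires ``aspect_ratio`` at or above the
false-positive threshold. Rejected records stay in the output, tagged with
the first criterion they failed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from .criteria import ShapeCriteria
from .errors import ValidationError

__all__ = ["MotifRecord", "measure_motifs", "classify", "records_to_table"]

_SQRT2 = float(np.sqrt(2.0))

# Moore neighborhood in clockwise order starting from West.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass(frozen=True)
class MotifRecord:
    """Shape descriptors of one segmented object."""

    label: int
    area: float
    perimeter: float
    circularity: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    length: float
    centroid: tuple[float, float]  # (row, col), 0-based
    motif_class: str = "unset"  # unset | cell_body | neurite | rejected
    reject_reason: str = ""  # area | circularity | aspect_ratio ('' if accepted)


def _trace_chain_perimeter(obj: np.ndarray) -> float:
    """Closed Moore-neighbor boundary trace of a single object image.

    Returns the chain length through boundary-pixel centers with √2 diagonal
    weights. Handles one-pixel and one-line objects (the trace walks out and
    back). ``obj`` is the object's padded binary subimage.
    """
    if obj.sum() == 1:
        return 4.0
    rows, cols = np.nonzero(obj)
    start = (int(rows[0]), int(cols[0]))  # raster-first pixel: nothing above/left
    p = start
    b = (start[0], start[1] - 1)  # entered from the West (background by raster order)
    length = 0.0
    first_move: tuple | None = None
    for _ in range(4 * obj.size + 8):
        db = _MOORE.index((b[0] - p[0], b[1] - p[1]))
        nxt = None
        for k in range(1, 9):  # scan clockwise starting just after the backtrack
            d = (db + k) % 8
            dr, dc = _MOORE[d]
            cand = (p[0] + dr, p[1] + dc)
            if obj[cand]:
                nxt = cand
                prev_bg = (p[0] + _MOORE[(d - 1) % 8][0], p[1] + _MOORE[(d - 1) % 8][1])
                step = _SQRT2 if dr != 0 and dc != 0 else 1.0
                break
        if nxt is None:  # defensive: isolated pixel
            return 4.0
        move = (p, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:  # Jacob's criterion: same pixel, same exit
            break
        length += step
        b, p = prev_bg, nxt
    return length


def _chain_perimeter(obj: np.ndarray) -> float:
    padded = np.pad(np.asarray(obj, bool), 1)
    return _trace_chain_perimeter(padded)


def _boundary_pixels(obj: np.ndarray) -> np.ndarray:
    """(n, 2) coordinates of object pixels with a background 8-neighbor."""
    obj = np.asarray(obj, bool)
    eroded = ndi.binary_erosion(obj, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(obj & ~eroded)


def _max_feret(points: np.ndarray) -> float:
    """Largest pairwise distance between pixel centers."""
    if len(points) == 1:
        return 1.0
    pts = points.astype(np.float64)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) — brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    return float(d.max())


def _skeleton_length(obj: np.ndarray) -> float:
    """Longest geodesic through the morphological skeleton.

    Skeleton pixels form a graph with unit/√2 edge weights; the length is
    the largest finite shortest-path distance from the farthest endpoint
    (double-sweep, exact on trees, a good lower bound on cyclic skeletons).
    """
    skel = skeletonize(np.asarray(obj, bool))
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return 1.0
    if len(coords) == 1:
        return 1.0
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    ii, jj, ww = [], [], []
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):  # each pair once
            j = index.get((r + dr, c + dc))
            if j is not None:
                ii.append(i)
                jj.append(j)
                ww.append(_SQRT2 if dr and dc else 1.0)
    n = len(coords)
    if not ii:
        return 1.0
    graph = coo_matrix(
        (np.array(ww + ww), (np.array(ii + jj), np.array(jj + ii))), shape=(n, n)
    ).tocsr()
    d0 = dijkstra(graph, directed=False, indices=0)
    d0[~np.isfinite(d0)] = -1
    far = int(np.argmax(d0))
    d1 = dijkstra(graph, directed=False, indices=far)
    d1[~np.isfinite(d1)] = -1
    far2 = int(np.argmax(d1))
    d2 = dijkstra(graph, directed=False, indices=far2)
    d2[~np.isfinite(d2)] = -1
    return float(max(d1.max(), d2.max(), 1.0))


def measure_motifs(labels: np.ndarray, length_method: str = "feret") -> list[MotifRecord]:
    """Measure every nonzero label of a label map.

    Parameters
    ----------
    labels
        2D integer label map (0 = background).
    length_method
        ``"feret"`` (max caliper over boundary pixels, default) or
        ``"skeleton"`` (longest skeleton geodesic, for curved neurites).
    """
    if length_method not in ("feret", "skeleton"):
        raise ValidationError(f"length_method must be 'feret' or 'skeleton', got {length_method!r}")
    labels = np.asarray(labels)
    records: list[MotifRecord] = []
    for prop in regionprops(labels):
        obj = prop.image  # tight binary subimage
        area = float(prop.area)
        perimeter = _chain_perimeter(obj)
        circularity = min(1.0, 4.0 * np.pi * area / perimeter**2) if perimeter > 0 else 1.0
        major = max(float(prop.axis_major_length), 1.0)
        minor = max(float(prop.axis_minor_length), 1.0)
        if area == 1.0:
            major = minor = 1.0
        if length_method == "feret":
            length = max(_max_feret(_boundary_pixels(obj)), 1.0)
        else:
            length = _skeleton_length(obj)
        records.append(
            MotifRecord(
                label=int(prop.label),
                area=area,
                perimeter=perimeter,
                circularity=circularity,
                major_axis=major,
                minor_axis=minor,
                aspect_ratio=major / minor,
                length=length,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    return records


def classify(
    motifs: list[MotifRecord], criteria: ShapeCriteria, pass_: str
) -> list[MotifRecord]:
    """Assign ``cell_body`` / ``neurite`` / ``rejected`` per the criteria.

    A pure, order-preserving filter: descriptors are never modified, and the
    output is a relabeled copy of the input list. The neurite pass applies
    the aspect-ratio false-positive filter after the area and circularity
    windows, so ``reject_reason == "aspect_ratio"`` identifies exactly the
    structures the filter removed.
    """
    if pass_ not in ("cell_body", "neurite"):
        raise ValidationError(f"pass_ must be 'cell_body' or 'neurite', got {pass_!r}")
    out: list[MotifRecord] = []
    for m in motifs:
        if pass_ == "cell_body":
            lo_a, hi_a = criteria.cell_body_area
            lo_c, hi_c = criteria.cell_body_circularity
            accept_class = "cell_body"
            ar_min = None
        else:
            lo_a, hi_a = criteria.neurite_area
            lo_c, hi_c = criteria.neurite_circularity
            accept_class = "neurite"
            ar_min = criteria.neurite_aspect_ratio_min
        if not (lo_a <= m.area <= hi_a):
            out.append(replace(m, motif_class="rejected", reject_reason="area"))
        elif not (lo_c <= m.circularity <= hi_c):
            out.append(replace(m, motif_class="rejected", reject_reason="circularity"))
        elif ar_min is not None and m.aspect_ratio < ar_min:
            out.append(replace(m, motif_class="rejected", reject_reason="aspect_ratio"))
        else:
            out.append(replace(m, motif_class=accept_class, reject_reason=""))
    return out


def records_to_table(records: list[MotifRecord]) -> "pd.DataFrame":
    """Flatten records into a DataFrame (centroid as two columns)."""
    import pandas as pd

    rows = []
    for m in records:
        rows.append(
            {
                "label": m.label,
                "area": m.area,
                "perimeter": m.perimeter,
                "circularity": m.circularity,
                "major_axis": m.major_axis,
                "minor_axis": m.minor_axis,
                "aspect_ratio": m.aspect_ratio,
                "length": m.length,
                "centroid_row": m.centroid[0],
                "centroid_col": m.centroid[1],
                "motif_class": m.motif_class,
                "reject_reason": m.reject_reason,
            }
        )
    columns = [
        "label", "area", "perimeter", "circularity", "major_axis", "minor_axis",
        "aspect_ratio", "length", "centroid_row", "centroid_col", "motif_class",
        "reject_reason",
    ]
    return pd.DataFrame(rows, columns=columns)
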
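"""Synthetic neuron-culture scenes with exact ground truth.

The generator emulates what a phase-contrast frame of a differentiating
neuronal culture looks like after idealization: roughly circular somata,
thin oblong neurites attached to soma boundaries at junction points, small
round debris specks, and additive Gaussian camera noise on two intensity
levels. Somata may be bright on dark or dark on bright (``polarity``).
Phase-contrast halos and intensity gradients are deliberately *not*
modeled; scenes are idealized so every ground-truth count and length is
exact by construction.

Geometry rules:

* somata are placed by rejection sampling with pairwise gaps ≥ 4 px;
* each neurite is a polyline grown from its parent soma boundary outward —
  per ~3 px step the heading changes by at most the ``curvature`` parameter
  (radians), so ``curvature=0`` gives straight bars; its true length is the
  polyline arc length;
* neurites are rendered as Bresenham polylines widened to 1–3 px, and a
  candidate that would touch unrelated foreground is re-drawn (bounded
  retries), so distinct motifs never merge;
* debris specks are sized below any sensible cell-body area minimum.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SceneSpec.seed``: equal specs give bitwise-identical images.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .errors import CapacityError, ValidationError
from .image import GrayImage

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "generate_touching_pair", "corpus"]

_STRUCT_8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic culture scene (all lengths in px)."""

    shape: tuple[int, int] = (512, 512)
    n_somata: int = 12
    soma_radius: tuple[int, int] = (8, 15)
    n_neurites_per_soma: tuple[int, int] = (0, 3)
    n_free_neurites: int = 0  # detached oblong structures (no junction)
    neurite_length: tuple[float, float] = (30.0, 120.0)
    neurite_width: int = 3
    curvature: float = 0.15  # max heading change (rad) per ~3 px growth step
    n_debris: int = 5
    debris_radius: tuple[int, int] = (1, 2)
    foreground: int = 200
    background: int = 30
    noise_sd: float = 3.0
    polarity: str = "bright"  # bright objects on dark bg, or the reverse
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("soma_radius", "n_neurites_per_soma", "neurite_length", "debris_radius"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValidationError(f"{name}: need 0 <= min <= max, got ({lo}, {hi})")
        if self.neurite_width not in (1, 2, 3):
            raise ValidationError("neurite_width must be 1, 2 or 3")
        if self.polarity not in ("bright", "dark"):
            raise ValidationError("polarity must be 'bright' or 'dark'")
        maxval = (1 << self.bit_depth) - 1
        for level in (self.foreground, self.background):
            if not (0 <= level <= maxval):
                raise ValidationError(f"intensity level {level} outside {self.bit_depth}-bit range")
        if self.foreground == self.background:
            raise ValidationError("foreground and background levels must differ")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact tables describing the drawn geometry."""

    somata: pd.DataFrame  # soma_id, row, col, radius
    neurites: pd.DataFrame  # neurite_id, soma_id (-1 if free), length, width, start_row, start_col
    junctions: pd.DataFrame  # junction_id, neurite_id, soma_id, row, col
    debris: pd.DataFrame  # debris_id, row, col, radius
    polylines: list[np.ndarray] = field(default_factory=list)  # float (n,2) per neurite

    @property
    def n_somata(self) -> int:
        return len(self.somata)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    m = np.zeros(shape, bool)
    rr, cc = skdraw.disk(center, radius + 0.5, shape=shape)
    m[rr, cc] = True
    return m


def _grow_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    length: float,
    curvature: float,
    shape: tuple[int, int],
    margin: float,
) -> np.ndarray | None:
    """Random-walk polyline of the requested arc length; None if it exits."""
    step = 3.0
    pts = [start.copy()]
    pos = start.copy()
    travelled = 0.0
    while travelled < length:
        seg = min(step, length - travelled)
        heading += rng.uniform(-curvature, curvature)
        pos = pos + seg * np.array([np.sin(heading), np.cos(heading)])
        if not (margin <= pos[0] < shape[0] - margin and margin <= pos[1] < shape[1] - margin):
            return None
        pts.append(pos.copy())
        travelled += seg
    return np.array(pts)


def _rasterize_polyline(poly: np.ndarray, width: int, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    ints = np.rint(poly).astype(int)
    for (r0, c0), (r1, c1) in zip(ints[:-1], ints[1:]):
        rr, cc = skdraw.line(r0, c0, r1, c1)
        mask[rr, cc] = True
    if width == 2:
        mask = ndi.binary_dilation(mask, structure=np.array([[1, 1], [1, 1]], bool))
    elif width == 3:
        mask = ndi.binary_dilation(mask, structure=_STRUCT_8)
    return mask


def _render(fg_mask: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> GrayImage:
    # the object level sits on the requested side of the background
    levels = (spec.foreground, spec.background)
    if spec.polarity == "bright":
        obj_level, bg_level = max(levels), min(levels)
    else:
        obj_level, bg_level = min(levels), max(levels)
    canvas = np.where(fg_mask, float(obj_level), float(bg_level))
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    maxval = (1 << spec.bit_depth) - 1
    pixels = np.clip(np.rint(canvas), 0, maxval).astype(np.int64)
    return GrayImage(pixels, bit_depth=spec.bit_depth)


def generate_scene(spec: SceneSpec, *, max_tries: int = 400) -> tuple[GrayImage, GroundTruth]:
    """Render one scene and its exact ground truth.

    Deterministic for a fixed spec (the seed drives all randomness). Raises
    :class:`CapacityError` when objects cannot be placed within the bounded
    retry budget — ask for fewer or smaller objects.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    occupied = np.zeros(shape, bool)  # all drawn foreground
    soma_masks: list[np.ndarray] = []

    # --- somata ---------------------------------------------------------
    soma_rows = []
    centers: list[tuple[float, float, float]] = []  # row, col, radius
    for sid in range(spec.n_somata):
        placed = False
        for _ in range(max_tries):
            r = int(rng.integers(spec.soma_radius[0], spec.soma_radius[1] + 1))
            margin = r + 3
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            if all(
                np.hypot(cy - oy, cx - ox) >= r + orad + 4 for oy, ox, orad in centers
            ):
                centers.append((cy, cx, r))
                m = _disk_mask(shape, (cy, cx), r)
                soma_masks.append(m)
                occupied |= m
                soma_rows.append({"soma_id": sid, "row": cy, "col": cx, "radius": r})
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place soma {sid + 1}/{spec.n_somata} in {shape}; "
                "request fewer or smaller objects"
            )

    # --- neurites -------------------------------------------------------
    neurite_rows, junction_rows, polylines = [], [], []
    nid = 0

    def _try_neurite(parent: int | None, used_angles: list[float]) -> bool:
        nonlocal nid, occupied
        lo_len, hi_len = spec.neurite_length
        for attempt in range(240):
            # late retries bias toward the short end of the requested range
            # and a smaller angular gap, so cramped somata stay feasible
            shrink = 1.0 if attempt < 80 else 0.5 if attempt < 160 else 0.25
            length = rng.uniform(lo_len, lo_len + (hi_len - lo_len) * shrink)
            min_gap = 1.0 if attempt < 120 else 0.5
            if parent is not None:
                cy, cx, r = centers[parent]
                angle = rng.uniform(0, 2 * np.pi)
                if any(
                    abs((angle - a + np.pi) % (2 * np.pi) - np.pi) < min_gap
                    for a in used_angles
                ):
                    continue
                start = np.array([cy + r * np.sin(angle), cx + r * np.cos(angle)])
                heading = angle
                own = ndi.binary_dilation(soma_masks[parent], _STRUCT_8, iterations=2)
            else:
                start = np.array(
                    [rng.uniform(8, shape[0] - 8), rng.uniform(8, shape[1] - 8)]
                )
                heading = rng.uniform(0, 2 * np.pi)
                own = np.zeros(shape, bool)
            poly = _grow_polyline(rng, start, heading, length, spec.curvature, shape, 4.0)
            if poly is None:
                continue
            mask = _rasterize_polyline(poly, spec.neurite_width, shape)
            # clearance to unrelated foreground must exceed the attachment
            # operator's reach (sobel band + 1 px dilation of both operands),
            # so detached structures can never register as junctions
            grown = ndi.binary_dilation(mask, _STRUCT_8, iterations=4)
            if (grown & occupied & ~own).any():
                continue
            occupied |= mask
            neurite_rows.append(
                {
                    "neurite_id": nid,
                    "soma_id": parent if parent is not None else -1,
                    "length": float(np.sum(np.hypot(*np.diff(poly, axis=0).T))),
                    "width": spec.neurite_width,
                    "start_row": float(poly[0, 0]),
                    "start_col": float(poly[0, 1]),
                }
            )
            if parent is not None:
                junction_rows.append(
                    {
                        "junction_id": len(junction_rows),
                        "neurite_id": nid,
                        "soma_id": parent,
                        "row": float(poly[0, 0]),
                        "col": float(poly[0, 1]),
                    }
                )
                used_angles.append(angle)
            polylines.append(poly)
            nid += 1
            return True
        return False

    for sid in range(spec.n_somata):
        n_target = int(
            rng.integers(spec.n_neurites_per_soma[0], spec.n_neurites_per_soma[1] + 1)
        )
        used_angles: list[float] = []
        for _ in range(n_target):
            if not _try_neurite(sid, used_angles):
                raise CapacityError(
                    f"could not attach a neurite to soma {sid}; scene too crowded"
                )
    for _ in range(spec.n_free_neurites):
        if not _try_neurite(None, []):
            raise CapacityError("could not place a free neurite; scene too crowded")

    # --- debris ---------------------------------------------------------
    debris_rows = []
    for did in range(spec.n_debris):
        placed = False
        for _ in range(max_tries):
            r = int(rng.integers(spec.debris_radius[0], spec.debris_radius[1] + 1))
            cy = rng.uniform(r + 3, shape[0] - r - 3)
            cx = rng.uniform(r + 3, shape[1] - r - 3)
            m = _disk_mask(shape, (cy, cx), r)
            if not (ndi.binary_dilation(m, _STRUCT_8, iterations=3) & occupied).any():
                occupied |= m
                debris_rows.append({"debris_id": did, "row": cy, "col": cx, "radius": r})
                placed = True
                break
        if not placed:
            raise CapacityError(f"could not place debris speck {did + 1}/{spec.n_debris}")

    truth = GroundTruth(
        somata=pd.DataFrame(soma_rows, columns=["soma_id", "row", "col", "radius"]),
        neurites=pd.DataFrame(
            neurite_rows,
            columns=["neurite_id", "soma_id", "length", "width", "start_row", "start_col"],
        ),
        junctions=pd.DataFrame(
            junction_rows, columns=["junction_id", "neurite_id", "soma_id", "row", "col"]
        ),
        debris=pd.DataFrame(debris_rows, columns=["debris_id", "row", "col", "radius"]),
        polylines=polylines,
    )
    return _render(occupied, spec, rng), truth


def generate_touching_pair(
    radius: int,
    center_distance: float,
    shape: tuple[int, int] = (96, 96),
    foreground: int = 200,
    background: int = 30,
    noise_sd: float = 3.0,
    polarity: str = "bright",
    bit_depth: int = 8,
    seed: int = 0,
) -> tuple[GrayImage, GroundTruth]:
    """Two overlapping somata rendered as one blob (watershed hard case).

    Requires ``center_distance < 2·radius`` so the disks genuinely overlap;
    a grazing pair (``2·radius − 1``) is allowed but is the documented hard
    boundary case. The pair's orientation is random (seeded).
    """
    if not center_distance < 2 * radius:
        raise ValidationError(
            f"center_distance {center_distance} must be < 2·radius ({2 * radius}) for overlap"
        )
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0, 2 * np.pi)
    mid = np.array([shape[0] / 2, shape[1] / 2])
    offset = (center_distance / 2) * np.array([np.sin(angle), np.cos(angle)])
    c1, c2 = mid - offset, mid + offset
    mask = _disk_mask(shape, tuple(c1), radius) | _disk_mask(shape, tuple(c2), radius)
    spec = SceneSpec(
        shape=shape,
        n_somata=0,
        n_debris=0,
        foreground=foreground,
        background=background,
        noise_sd=noise_sd,
        polarity=polarity,
        bit_depth=bit_depth,
        seed=seed,
    )
    somata = pd.DataFrame(
        [
            {"soma_id": 0, "row": c1[0], "col": c1[1], "radius": radius},
            {"soma_id": 1, "row": c2[0], "col": c2[1], "radius": radius},
        ]
    )
    empty_n = pd.DataFrame(columns=["neurite_id", "soma_id", "length", "width", "start_row", "start_col"])
    empty_j = pd.DataFrame(columns=["junction_id", "neurite_id", "soma_id", "row", "col"])
    empty_d = pd.DataFrame(columns=["debris_id", "row", "col", "radius"])
    return _render(mask, spec, rng), GroundTruth(somata, empty_n, empty_j, empty_d)


def corpus() -> dict[str, SceneSpec]:
    """Named fixture scenes exercising every pipeline stage.

    Touching-pair hard cases are produced by :func:`generate_touching_pair`
    and are therefore not part of this table.
    """
    base = SceneSpec()
    return {
        "sparse_somata": replace(base, n_somata=8, n_neurites_per_soma=(0, 0), seed=101),
        "dense_somata": replace(base, n_somata=30, n_neurites_per_soma=(0, 0), seed=102),
        "somata_noiseless": replace(
            base, n_somata=6, n_neurites_per_soma=(0, 0), n_debris=0, noise_sd=0.0, seed=103
        ),
        "somata_with_neurites": replace(base, n_somata=6, n_neurites_per_soma=(1, 3), seed=104),
        "junction_scene": replace(
            base, n_somata=3, n_neurites_per_soma=(2, 2), n_debris=0, seed=105
        ),
        "free_bars": replace(
            base,
            n_somata=0,
            n_free_neurites=8,
            curvature=0.0,
            n_debris=0,
            seed=106,
        ),
        "curved_neurites": replace(
            base, n_somata=0, n_free_neurites=6, curvature=0.25, n_debris=0, seed=107
        ),
        "debris_field": replace(
            base, n_somata=5, n_neurites_per_soma=(0, 0), n_debris=25, seed=108
        ),
        "dark_polarity": replace(
            base, n_somata=8, n_neurites_per_soma=(0, 2), polarity="dark", seed=109
        ),
        "high_noise": replace(base, n_somata=10, n_neurites_per_soma=(0, 2), noise_sd=8.0, seed=110),
        "sixteen_bit": replace(
            base,
            n_somata=8,
            n_neurites_per_soma=(0, 2),
            bit_depth=16,
            foreground=48000,
            background=6000,
            noise_sd=600.0,
            seed=111,
        ),
        "mixed_full": replace(
            base, n_somata=10, n_neurites_per_soma=(0, 3), n_free_neurites=3, n_debris=10, seed=112
        ),
    }
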
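"""Per-cell-type admission criteria for motif classification.

Cultured neuronal cell types differ widely in soma size and shape — chick
cerebellar granule neurons are small and round, NT2 neurons oblong, PC12
somata larger — so the size/circularity windows that decide what counts as
a cell body or a neurite are a per-cell-type configuration, not a constant.

The named presets below are starting points to be calibrated against a
manual consensus count for each new imaging setup (magnification and camera
binning change every pixel-area bound). Load a user-edited YAML file with
:func:`load_criteria` for production analyses. The ``synthetic`` preset
matches the geometry of :mod:`neuromorph.synthetic` scenes and is the
default for tests and examples.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["ShapeCriteria", "PRESETS", "get_preset", "load_criteria", "save_criteria"]


@dataclass(frozen=True)
class ShapeCriteria:
    """Admission windows for the two classification passes.

    Areas are px², circularity is ``4πA/P²`` in [0, 1], and
    ``neurite_aspect_ratio_min`` is the false-positive filter: any neurite
    candidate with a smaller major/minor axis ratio is rejected.
    """

    cell_body_area: tuple[float, float] = (80.0, 2500.0)
    cell_body_circularity: tuple[float, float] = (0.55, 1.0)
    neurite_area: tuple[float, float] = (25.0, 1.0e5)
    neurite_circularity: tuple[float, float] = (0.0, 0.55)
    neurite_aspect_ratio_min: float = 2.5

    def __post_init__(self) -> None:
        for name in ("cell_body_area", "cell_body_circularity", "neurite_area", "neurite_circularity"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValidationError(f"{name}: need 0 <= min <= max, got ({lo}, {hi})")
            object.__setattr__(self, name, (float(lo), float(hi)))
        if not self.neurite_aspect_ratio_min >= 1:
            raise ValidationError("neurite_aspect_ratio_min must be >= 1")


#: Named presets. The synthetic preset is exact for the generator's geometry;
#: the cell-line presets are plausible IncuCyte-scale defaults that users
#: should recalibrate (soma pixel area depends on optics, not biology alone).
PRESETS: dict[str, ShapeCriteria] = {
    "synthetic": ShapeCriteria(),
    "cgn": ShapeCriteria((30.0, 400.0), (0.6, 1.0), (15.0, 1.0e5), (0.0, 0.5), 2.0),
    "pc12n": ShapeCriteria((100.0, 3000.0), (0.55, 1.0), (25.0, 1.0e5), (0.0, 0.5), 2.0),
    "nt2n": ShapeCriteria((80.0, 2500.0), (0.4, 1.0), (25.0, 1.0e5), (0.0, 0.5), 2.0),
    "shsy5y": ShapeCriteria((60.0, 1500.0), (0.55, 1.0), (20.0, 1.0e5), (0.0, 0.5), 2.0),
    "mouse_primary": ShapeCriteria((50.0, 1200.0), (0.55, 1.0), (20.0, 1.0e5), (0.0, 0.5), 2.0),
}


def get_preset(name: str) -> ShapeCriteria:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown cell-type preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def load_criteria(path: str | Path) -> ShapeCriteria:
    """Load criteria from a YAML mapping (same keys as :class:`ShapeCriteria`)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: criteria file must be a mapping")
    kwargs = {}
    for key in ("cell_body_area", "cell_body_circularity", "neurite_area", "neurite_circularity"):
        if key in data:
            kwargs[key] = tuple(data[key])
    if "neurite_aspect_ratio_min" in data:
        kwargs["neurite_aspect_ratio_min"] = float(data["neurite_aspect_ratio_min"])
    unknown = set(data) - {*kwargs, "neurite_aspect_ratio_min"}
    unknown -= set(kwargs)
    if unknown:
        raise ValidationError(f"{path}: unknown criteria keys {sorted(unknown)}")
    return ShapeCriteria(**kwargs)


def save_criteria(criteria: ShapeCriteria, path: str | Path) -> Path:
    data = asdict(criteria)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return Path(path)
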
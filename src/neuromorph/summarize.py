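"""Per-image summaries and replicate-aggregated time courses.

Each analysed image reduces to one :class:`ImageSummary` row: counts of
accepted cell bodies, neurites and attachment points plus arithmetic means
of the per-motif descriptors. A metric whose class is empty is *absent*
(``None`` / empty CSV cell), never zero — a zero would bias time-course
means downward.

Time-course aggregation is two-stage by default, mirroring a plate design
of several imaged areas per well: area-level summaries are averaged within
each well first, then the mean and sample standard deviation (n−1) are
taken over wells per (condition, time point, metric). Set
``group_by="area"`` to treat every image as its own replicate instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attachment import AttachmentPointSet
from .errors import ValidationError
from .io import Manifest
from .morphometry import MotifRecord

__all__ = ["ImageSummary", "summarize_image", "summaries_to_table", "aggregate_timecourse"]

#: Metrics carried into the time-course aggregation.
TIMECOURSE_METRICS = (
    "n_cell_bodies",
    "mean_cell_body_area",
    "mean_cell_body_circularity",
    "n_neurites",
    "mean_neurite_length",
    "mean_neurite_aspect_ratio",
    "n_attachment_points",
)


@dataclass(frozen=True)
class ImageSummary:
    """Mean metric values and counts for one image."""

    image_id: str
    n_cell_bodies: int
    mean_cell_body_area: float | None
    mean_cell_body_circularity: float | None
    mean_cell_body_aspect_ratio: float | None
    n_neurites: int
    mean_neurite_length: float | None
    mean_neurite_area: float | None
    mean_neurite_circularity: float | None
    mean_neurite_aspect_ratio: float | None
    n_attachment_points: int


def _mean(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def summarize_image(
    image_id: str,
    cell_bodies: list[MotifRecord],
    neurites: list[MotifRecord],
    attachments: AttachmentPointSet | None = None,
) -> ImageSummary:
    """Reduce one image's accepted records to counts and means.

    Rejected-class records are ignored here (they stay in the per-motif
    CSVs), so callers may pass either pre-filtered lists or full ones.
    """
    cb = [m for m in cell_bodies if m.motif_class == "cell_body"]
    nr = [m for m in neurites if m.motif_class == "neurite"]
    return ImageSummary(
        image_id=image_id,
        n_cell_bodies=len(cb),
        mean_cell_body_area=_mean([m.area for m in cb]),
        mean_cell_body_circularity=_mean([m.circularity for m in cb]),
        mean_cell_body_aspect_ratio=_mean([m.aspect_ratio for m in cb]),
        n_neurites=len(nr),
        mean_neurite_length=_mean([m.length for m in nr]),
        mean_neurite_area=_mean([m.area for m in nr]),
        mean_neurite_circularity=_mean([m.circularity for m in nr]),
        mean_neurite_aspect_ratio=_mean([m.aspect_ratio for m in nr]),
        n_attachment_points=attachments.count if attachments is not None else 0,
    )


def summaries_to_table(summaries: list[ImageSummary]) -> pd.DataFrame:
    cols = [
        "image_id",
        "n_cell_bodies",
        "mean_cell_body_area",
        "mean_cell_body_circularity",
        "mean_cell_body_aspect_ratio",
        "n_neurites",
        "mean_neurite_length",
        "mean_neurite_area",
        "mean_neurite_circularity",
        "mean_neurite_aspect_ratio",
        "n_attachment_points",
    ]
    table = pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries], columns=cols)
    for c in cols:
        if c.startswith("mean_"):  # absent mean -> NaN (empty CSV cell), never 0
            table[c] = table[c].astype(float)
        elif c.startswith("n_"):
            table[c] = table[c].astype(np.int64)
    return table


def aggregate_timecourse(
    summaries: list[ImageSummary],
    manifest: Manifest,
    group_by: str = "well",
) -> pd.DataFrame:
    """Aggregate per-image summaries into long-format time-course rows.

    Returns a DataFrame with columns
    ``condition, time_h, metric, mean, sd, n`` where ``n`` is the number of
    replicate groups (wells by default), ``mean``/``sd`` are the replicate
    mean and sample standard deviation (n−1 denominator; ``sd`` is absent
    when n < 2). Input order never affects any output number: rows are
    sorted by (condition, time_h, metric).
    """
    if group_by not in ("well", "area"):
        raise ValidationError(f"group_by must be 'well' or 'area', got {group_by!r}")
    meta = manifest.rows.assign(image_id=[Path(p).stem for p in manifest.rows["path"]])
    table = summaries_to_table(summaries)
    orphans = sorted(set(table["image_id"]) - set(meta["image_id"]))
    if orphans:
        raise ValidationError(f"summaries not present in manifest: {orphans}")
    # canonical row order so float accumulation is permutation-invariant
    merged = table.merge(meta, on="image_id", how="left").sort_values(
        "image_id", kind="mergesort"
    )

    if group_by == "well":
        # stage 1: mean over areas within each well (NaN = absent, skipped)
        replicate = (
            merged.groupby(["condition", "time_h", "well_id"], sort=True)[list(TIMECOURSE_METRICS)]
            .mean()
            .reset_index()
        )
    else:
        replicate = merged.rename(columns={"area_id": "replicate_id"})[
            ["condition", "time_h", "replicate_id", *TIMECOURSE_METRICS]
        ]

    long = replicate.melt(
        id_vars=["condition", "time_h"],
        value_vars=list(TIMECOURSE_METRICS),
        var_name="metric",
        value_name="value",
    ).dropna(subset=["value"])
    grouped = long.groupby(["condition", "time_h", "metric"], sort=True)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    out = out.sort_values(["condition", "time_h", "metric"], kind="mergesort").reset_index(drop=True)
    return out[["condition", "time_h", "metric", "mean", "sd", "n"]]
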
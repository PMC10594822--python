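"""Reading images and masks, writing masks and CSV tables.

All CSV output uses one fixed dialect — comma separated, header row, UTF-8,
``.`` decimal separator, empty cell for missing values — so runs diff
byte-for-byte. Coordinates everywhere are 0-based ``(row, col)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .image import GrayImage

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_csv",
    "read_csv",
    "Manifest",
    "read_manifest",
]

#: Manifest columns, in on-disk order.
MANIFEST_COLUMNS = ("path", "well_id", "area_id", "time_h", "condition")


def _load_plane(path: Path) -> tuple[np.ndarray, int]:
    """Read the first 2D plane of a TIFF/PNG file; return (array, bit depth)."""
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    depth = 8 if arr.dtype.itemsize == 1 else 16
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance
        rgb = arr[..., :3].astype(np.float64)
        arr = np.rint(rgb @ np.array([0.299, 0.587, 0.114])).astype(np.int64)
    elif arr.ndim == 3:  # stack: first plane, warn
        warnings.warn(
            f"{path.name}: {arr.shape[0]}-plane stack, using the first plane",
            stacklevel=3,
        )
        arr = arr[0]
    if arr.size == 0:  # tifffile yields an empty array for truncated data
        raise OSError(f"{path}: empty or truncated image data")
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2D plane, got shape {arr.shape}")
    return arr, depth


def read_image(path: str | Path) -> GrayImage:
    """Read a TIFF or PNG into a :class:`GrayImage`.

    Bit depth is inferred from the stored dtype (anything wider than 8 bits
    maps to 16). RGB input is converted to ITU-R 601 luminance. Multi-page
    TIFFs yield their first plane with a warning.
    """
    path = Path(path)
    try:
        arr, depth = _load_plane(path)
    except (OSError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise OSError(f"could not read image {path}: {exc}") from exc
    return GrayImage(arr.astype(np.int64), bit_depth=depth)


def write_image(image: GrayImage, path: str | Path) -> Path:
    """Write a :class:`GrayImage` as TIFF or PNG at its native bit depth."""
    path = Path(path)
    native = image.astype_native()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, native)
    else:
        iio.imwrite(path, native)
    return path


def read_mask(path: str | Path, foreground: str = "white") -> np.ndarray:
    """Read a pre-segmented two-level image as a boolean mask.

    Parameters
    ----------
    foreground
        ``"white"`` if objects are the brighter level, ``"black"`` if darker.
        The returned mask is always ``True`` on objects regardless of the
        on-disk convention.

    Raises
    ------
    ValidationError
        If the image holds more than two distinct intensities.
    """
    if foreground not in ("white", "black"):
        raise ValidationError(f"foreground must be 'white' or 'black', got {foreground!r}")
    image = read_image(path)
    values = np.unique(image.pixels)
    if values.size > 2:
        raise ValidationError(
            f"{path}: mask image has {values.size} distinct values, expected at most 2"
        )
    if values.size == 1:
        # Degenerate but allowed: decide by comparing to the depth midpoint.
        is_high = values[0] > image.max_value // 2
        fill = is_high if foreground == "white" else not is_high
        return np.full(image.shape, bool(fill))
    hi = values[1]
    mask = image.pixels == hi
    return mask if foreground == "white" else ~mask


def write_mask(mask: np.ndarray, path: str | Path, foreground: str = "white") -> Path:
    """Write a boolean mask as an 8-bit two-level image (0/255)."""
    mask = np.asarray(mask, bool)
    arr = np.where(mask, 255, 0) if foreground == "white" else np.where(mask, 0, 255)
    return write_image(GrayImage(arr.astype(np.int64), bit_depth=8), path)


def write_csv(rows: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write a record table in the fixed CSV dialect.

    Missing values become empty cells; floats use Python repr so a
    write-then-read round trip is lossless.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    path = Path(path)
    try:
        df.to_csv(path, index=False, na_rep="", lineterminator="\n")
    except OSError as exc:
        raise OSError(f"could not write CSV {path}: {exc}") from exc
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (empty cells become NaN)."""
    return pd.read_csv(path)


@dataclass(frozen=True)
class Manifest:
    """Plate layout for time-course experiments.

    One row per image file: ``path, well_id, area_id, time_h, condition``.
    ``time_h`` is hours since plating, taken verbatim (never parsed from
    filenames). Paths are unique and, at load time, must exist.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if df["path"].duplicated().any():
            dupes = df.loc[df["path"].duplicated(), "path"].tolist()
            raise ValidationError(f"manifest paths not unique: {dupes}")
        if (df["time_h"].astype(float) < 0).any():
            raise ValidationError("manifest time_h must be >= 0")

    @property
    def image_ids(self) -> list[str]:
        """File stems, the key used to join per-image summaries."""
        return [Path(p).stem for p in self.rows["path"]]

    def paths(self) -> list[Path]:
        return [Path(p) for p in self.rows["path"]]


def read_manifest(path: str | Path, check_files: bool = True) -> Manifest:
    """Load a manifest CSV; optionally verify every referenced file exists."""
    base = Path(path).parent
    df = pd.read_csv(path)
    if "path" in df.columns:
        df = df.assign(path=[str((base / p)) if not Path(p).is_absolute() else str(p)
                             for p in df["path"]])
    manifest = Manifest(df)
    if check_files:
        gone = [p for p in manifest.paths() if not p.exists()]
        if gone:
            raise ValidationError(f"manifest references missing files: {gone}")
    return manifest
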
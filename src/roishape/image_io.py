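"""Reading segmented rasters and writing feature tables.

Segmented images are integer category matrices with at most three classes
(e.g. background / non-malignant / malignant in pathology maps).  The
coordinate convention shared by every module is 0-based row-major with the
origin at the top-left corner; the row index increases downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SegmentedImage",
    "BinaryImage",
    "TooManyClassesError",
    "AmbiguousChannelsError",
    "read_segmented_image",
    "binarize",
    "write_feature_table",
    "read_feature_table",
    "write_label_map_png",
]

MAX_CLASSES = 3


class TooManyClassesError(ValueError):
    """Raised when a raster decodes to more than three distinct categories."""


class AmbiguousChannelsError(ValueError):
    """Raised for RGB rasters whose channels disagree and no class_map is given."""


@dataclass(frozen=True)
class SegmentedImage:
    """An integer category matrix with at most three classes.

    Parameters
    ----------
    pixels
        2-D integer array of category codes in ``{0, ..., n_classes - 1}``.
    source_id
        Free-text identifier for the originating image (defaults to "").
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be integer-valued")
        values = np.unique(px)
        if values.min() < 0:
            raise ValueError("category codes must be non-negative")
        n = int(values.max()) + 1
        if n > MAX_CLASSES:
            raise TooManyClassesError(
                f"too many classes: {n} categories, at most {MAX_CLASSES} supported"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.pixels.max()) + 1 if self.pixels.max() > 0 else 2

    @property
    def categories(self) -> set[int]:
        return set(int(v) for v in np.unique(self.pixels))


@dataclass(frozen=True)
class BinaryImage:
    """A {0, 1} foreground mask."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if not np.issubdtype(px.dtype, np.integer):
            px = px.astype(np.int64)
        if not np.isin(px, (0, 1)).all():
            raise ValueError("binary image pixels must be 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


def _decode_raster(path: Path) -> np.ndarray:
    """Decode PNG/GIF into a single-channel integer array.

    Multi-channel rasters are collapsed to one channel only when every channel
    is identical; otherwise the caller must disambiguate with ``class_map``.
    """
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB") if im.mode == "P" else im)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop a fully-opaque alpha channel
            if not (arr[..., 3] == arr[0, 0, 3]).all():
                raise AmbiguousChannelsError(
                    f"{path}: alpha channel varies; provide a class_map"
                )
            arr = arr[..., :3]
        if not ((arr[..., 0] == arr[..., 1]).all() and (arr[..., 0] == arr[..., 2]).all()):
            raise AmbiguousChannelsError(
                f"{path}: RGB channels differ; provide a class_map"
            )
        arr = arr[..., 0]
    return arr.astype(np.int64)


def read_segmented_image(
    path: str | Path,
    class_map: Mapping[int, int] | None = None,
) -> SegmentedImage:
    """Read a PNG/GIF raster or whitespace-delimited integer matrix text file.

    Distinct raster values are mapped to consecutive category codes.  Without
    an explicit ``class_map`` the distinct values, sorted ascending, become
    categories 0, 1, 2 — the smallest (darkest) value is background.

    Raises
    ------
    TooManyClassesError
        If the raster holds more than three distinct values after mapping.
    AmbiguousChannelsError
        If an RGB raster has non-identical channels and no ``class_map``.
    OSError
        If the file cannot be read or decoded.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".png", ".gif"}:
        raw = _decode_raster(path)
    else:
        raw = np.loadtxt(path, dtype=np.int64, ndmin=2)

    values = np.unique(raw)
    if class_map is not None:
        try:
            lut = {int(v): int(class_map[int(v)]) for v in values}
        except KeyError as exc:
            raise ValueError(f"class_map is missing raster value {exc.args[0]}") from exc
        mapped = np.vectorize(lut.__getitem__, otypes=[np.int64])(raw)
        n_distinct = len(set(lut.values()))
    else:
        if len(values) > MAX_CLASSES:
            raise TooManyClassesError(
                f"too many classes: raster has {len(values)} distinct values, "
                f"at most {MAX_CLASSES} supported"
            )
        mapped = np.searchsorted(values, raw).astype(np.int64)
        n_distinct = len(values)
    if n_distinct > MAX_CLASSES:
        raise TooManyClassesError(
            f"too many classes: {n_distinct} categories after mapping"
        )
    return SegmentedImage(pixels=mapped, source_id=path.stem)


def binarize(image: SegmentedImage, foreground_categories: Iterable[int]) -> BinaryImage:
    """Collapse a segmented image to a foreground mask.

    ``foreground_categories`` must be a non-empty strict subset of the image's
    categories; everything else (including classes treated as holes inside the
    tissue, per the three-class convention) becomes background.
    """
    fg = set(int(c) for c in foreground_categories)
    cats = image.categories
    if not fg:
        raise ValueError("foreground_categories must be non-empty")
    if not fg < cats:
        raise ValueError(
            f"foreground_categories {sorted(fg)} must be a strict subset of "
            f"the image categories {sorted(cats)}"
        )
    mask = np.isin(image.pixels, sorted(fg)).astype(np.uint8)
    return BinaryImage(pixels=mask)


def write_segmented_image(image: SegmentedImage, path: str | Path) -> None:
    """Write the category matrix as whitespace-delimited integer text."""
    np.savetxt(path, image.pixels, fmt="%d")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV: image_id, region_label, then the 29 features.

    Floats are rendered with shortest round-trip precision, so reading the CSV
    back reproduces the values bit-for-bit.
    """
    from .feature_extraction import FEATURE_NAMES  # local import: avoid cycle

    cols = ["image_id", "region_label", *FEATURE_NAMES]
    if table.empty:
        out = pd.DataFrame(columns=cols)
    else:
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        out = table.loc[:, cols]
    # repr gives the shortest decimal text that round-trips to the same float
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_feature_table`."""
    from .feature_extraction import FEATURE_NAMES

    # round_trip parsing: the default float parser can be one ulp off
    df = pd.read_csv(path, dtype={"image_id": str}, float_precision="round_trip")
    expected = ["image_id", "region_label", *FEATURE_NAMES]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected feature-table columns in {path}")
    return df


def write_label_map_png(labels: np.ndarray, path: str | Path) -> None:
    """Export a label map as 8-bit grayscale PNG for visual inspection.

    Label 0 (background) maps to black; labels 1..k are spread over distinct
    gray levels up to white.
    """
    labels = np.asarray(labels)
    k = int(labels.max())
    if k == 0:
        gray = np.zeros_like(labels, dtype=np.uint8)
    else:
        lut = np.zeros(k + 1, dtype=np.uint8)
        lut[1:] = np.linspace(255, 64, k).round().astype(np.uint8)
        gray = lut[labels]
    Image.fromarray(gray, mode="L").save(path)
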
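"""Connected-component ROI labelling, filtering and size ordering.

Foreground regions are maximal 4-connected components (edge adjacency only;
diagonal contact does not join regions).  Labels are assigned from largest to
smallest pixel count, so label 1 is always the dominant region of the image —
the reference region for the quarter-rule quality-control filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import BinaryImage

__all__ = [
    "RegionLabelMap",
    "label_regions",
    "filter_regions",
    "qc_filter_quarter_rule",
]

# 4-connectivity structuring element (edge neighbours only).
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class RegionLabelMap:
    """Integer label matrix with regions 1..k in non-increasing area order.

    ``areas[i]`` is the pixel count of label ``i + 1``; background is 0.
    """

    labels: np.ndarray
    areas: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = np.ascontiguousarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D matrix")
        k = len(self.areas)
        if labels.max(initial=0) != k:
            raise ValueError("label values must be exactly 1..k with no gaps")
        if any(self.areas[i] < self.areas[i + 1] for i in range(k - 1)):
            raise ValueError("areas must be non-increasing")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "areas", tuple(int(a) for a in self.areas))

    @property
    def k(self) -> int:
        return len(self.areas)

    def area_of(self, label: int) -> int:
        if not 1 <= label <= self.k:
            raise ValueError(f"label {label} out of range 1..{self.k}")
        return self.areas[label - 1]


def label_regions(image: BinaryImage) -> RegionLabelMap:
    """Label maximal 4-connected foreground components, largest first.

    Equal-area ties are broken by raster-scan order of each region's
    topmost-leftmost pixel, which makes relabelling reproducible.  An
    all-background image yields ``k = 0``.
    """
    raw, n = ndimage.label(image.pixels, structure=_STRUCTURE_4)
    if n == 0:
        return RegionLabelMap(labels=np.zeros_like(image.pixels, dtype=np.int32), areas=())
    counts = np.bincount(raw.ravel(), minlength=n + 1)[1:]
    # scipy assigns raw labels in raster-scan order of first appearance, so a
    # stable sort on -area keeps the raster-order tie-break for equal areas.
    order = np.argsort(-counts, kind="stable")
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[order + 1] = np.arange(1, n + 1, dtype=np.int32)
    return RegionLabelMap(labels=lut[raw], areas=tuple(int(counts[i]) for i in order))


def _relabel_keep(label_map: RegionLabelMap, keep: list[int]) -> RegionLabelMap:
    """Relabel the surviving labels 1..k' preserving their size order."""
    lut = np.zeros(label_map.k + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        lut[old] = new
    return RegionLabelMap(
        labels=lut[label_map.labels],
        areas=tuple(label_map.areas[old - 1] for old in keep),
    )


def filter_regions(
    label_map: RegionLabelMap,
    min_area: int | None = None,
    top_n: int | None = None,
) -> RegionLabelMap:
    """Keep regions by minimum net area OR the largest ``n`` regions.

    The two filtering methods are alternatives, not composable: exactly one of
    ``min_area``/``top_n`` must be given.  Survivors are relabelled 1..k'
    preserving size order; their pixel sets are untouched.
    """
    if (min_area is None) == (top_n is None):
        raise ValueError("provide exactly one of min_area or top_n")
    if min_area is not None:
        if min_area < 1:
            raise ValueError("min_area must be >= 1")
        keep = [lbl for lbl in range(1, label_map.k + 1)
                if label_map.areas[lbl - 1] >= min_area]
    else:
        assert top_n is not None
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        keep = list(range(1, min(top_n, label_map.k) + 1))
    return _relabel_keep(label_map, keep)


def qc_filter_quarter_rule(label_map: RegionLabelMap) -> RegionLabelMap:
    """Drop regions whose net area is less than one-fourth of the largest ROI.

    The comparison is strict: a region at exactly one quarter of the largest
    area is kept.  The largest region always survives.  Requires ``k >= 1``.
    """
    if label_map.k == 0:
        raise ValueError("quarter-rule QC requires at least one region")
    threshold = label_map.areas[0] / 4.0
    keep = [lbl for lbl in range(1, label_map.k + 1)
            if not label_map.areas[lbl - 1] < threshold]
    return _relabel_keep(label_map, keep)
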
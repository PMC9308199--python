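"""End-to-end pipeline: segmented image -> per-region shape feature table.

The surface is a stateless scikit-learn transformer so the extractor composes
with sklearn pipelines and model selection; the module-level
:func:`run_pipeline` is a thin file-oriented wrapper used by the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import image_io
from .feature_extraction import (
    FEATURE_NAMES,
    FeatureConfig,
    aggregate_slide,
    compute_features,
)
from .image_io import BinaryImage, SegmentedImage, binarize, read_segmented_image
from .roi_labelling import filter_regions, label_regions, qc_filter_quarter_rule

__all__ = ["ShapeFeatureExtractor", "RunConfig", "run_pipeline"]

logger = logging.getLogger("roishape")


class ShapeFeatureExtractor(TransformerMixin, BaseEstimator):
    """Extract the 29 shape features from segmented images.

    A stateless transformer: ``fit`` only validates parameters.  ``transform``
    accepts a list of segmented images (``SegmentedImage``, ``BinaryImage`` or
    2-D integer arrays) and returns a tidy ``DataFrame`` with one row per
    region (or per image when ``aggregate=True``).

    Parameters
    ----------
    foreground : sequence of int, default=(1,)
        Category codes treated as foreground when binarizing multi-class
        input.  Binary input with foreground ``{1}`` passes through unchanged.
    min_area : int or None
        Keep only regions with at least this many pixels (exclusive with
        ``top_n``).
    top_n : int or None
        Keep only the ``n`` largest regions (exclusive with ``min_area``).
    qc_quarter_rule : bool, default=False
        Drop regions smaller than one quarter of the image's largest region.
    aggregate : bool, default=False
        Average features at the image (slide) level, ignoring missing values.
    entropy_bins, protrusion_depth_threshold, degenerate_area_threshold,
    circularity_area_choice
        Feature-definition knobs; see
        :class:`roishape.feature_extraction.FeatureConfig`.
    """

    def __init__(
        self,
        foreground: Sequence[int] = (1,),
        min_area: int | None = None,
        top_n: int | None = None,
        qc_quarter_rule: bool = False,
        aggregate: bool = False,
        entropy_bins: int = 10,
        protrusion_depth_threshold: float = 2.0,
        degenerate_area_threshold: int = 5,
        circularity_area_choice: str = "filled",
    ) -> None:
        self.foreground = foreground
        self.min_area = min_area
        self.top_n = top_n
        self.qc_quarter_rule = qc_quarter_rule
        self.aggregate = aggregate
        self.entropy_bins = entropy_bins
        self.protrusion_depth_threshold = protrusion_depth_threshold
        self.degenerate_area_threshold = degenerate_area_threshold
        self.circularity_area_choice = circularity_area_choice

    # -- sklearn plumbing ---------------------------------------------------

    def _validate_params(self) -> FeatureConfig:
        if self.min_area is not None and self.top_n is not None:
            raise ValueError("min_area and top_n are exclusive filter modes")
        if not self.foreground:
            raise ValueError("foreground must name at least one category")
        return FeatureConfig(
            entropy_bins=self.entropy_bins,
            protrusion_depth_threshold=self.protrusion_depth_threshold,
            degenerate_area_threshold=self.degenerate_area_threshold,
            circularity_area_choice=self.circularity_area_choice,
        )

    def fit(self, X: Iterable | None = None, y=None) -> "ShapeFeatureExtractor":
        """Validate parameters; the transformer learns nothing from data."""
        self._validate_params()
        self.feature_names_ = list(FEATURE_NAMES)
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)

    # -- the pipeline -------------------------------------------------------

    def _coerce_binary(self, image, idx: int) -> tuple[BinaryImage, str]:
        if isinstance(image, BinaryImage):
            return image, f"image-{idx}"
        if isinstance(image, np.ndarray):
            image = SegmentedImage(pixels=np.asarray(image), source_id=f"image-{idx}")
        if not isinstance(image, SegmentedImage):
            raise TypeError(f"unsupported input type {type(image).__name__}")
        image_id = image.source_id or f"image-{idx}"
        fg = set(int(c) for c in self.foreground)
        if image.categories == {0, 1} and fg == {1}:
            return BinaryImage(pixels=image.pixels), image_id
        return binarize(image, fg), image_id

    def transform_one(self, image, image_id: str | None = None) -> pd.DataFrame:
        """Run the full per-image pipeline and return the per-region table."""
        config = self._validate_params()
        binary, default_id = self._coerce_binary(image, 0)
        image_id = image_id or default_id

        label_map = label_regions(binary)
        logger.info("%s: %d region(s) labelled", image_id, label_map.k)
        if self.min_area is not None or self.top_n is not None:
            before = label_map.k
            label_map = filter_regions(label_map, min_area=self.min_area,
                                       top_n=self.top_n)
            logger.info("%s: size filter dropped %d region(s)",
                        image_id, before - label_map.k)
        if self.qc_quarter_rule and label_map.k > 0:
            before = label_map.k
            label_map = qc_filter_quarter_rule(label_map)
            logger.info("%s: quarter-rule QC dropped %d region(s)",
                        image_id, before - label_map.k)
        return compute_features(label_map, image_id, config)

    def transform(self, X: Iterable) -> pd.DataFrame:
        """Per-region feature table for a list of images.

        With ``aggregate=True`` the result has one row per image: the
        slide-level feature means plus the contributing region count.
        """
        self.fit(X)
        tables = [self.transform_one(img, None if not isinstance(img, SegmentedImage)
                                     else (img.source_id or None))
                  for img in X]
        table = (pd.concat(tables, ignore_index=True) if tables
                 else pd.DataFrame(columns=["image_id", "region_label", *FEATURE_NAMES]))
        if not self.aggregate:
            return table
        agg_rows = []
        for t in tables:
            if t.empty:
                continue
            row = aggregate_slide(t)
            row["image_id"] = t["image_id"].iloc[0]
            agg_rows.append(row)
        agg = pd.DataFrame(agg_rows)
        cols = ["image_id", *FEATURE_NAMES, "n_regions"]
        return agg.loc[:, cols] if not agg.empty else pd.DataFrame(columns=cols)


@dataclass
class RunConfig:
    """File-level pipeline configuration for the CLI."""

    inputs: tuple[Path, ...]
    out: Path
    foreground: tuple[int, ...] = (1,)
    class_map: dict[int, int] | None = None
    min_area: int | None = None
    top_n: int | None = None
    qc_quarter_rule: bool = False
    aggregate: bool = False
    labels_out: Path | None = None
    feature_overrides: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Read each input, run the pipeline, and write the CSV feature table."""
    extractor = ShapeFeatureExtractor(
        foreground=config.foreground,
        min_area=config.min_area,
        top_n=config.top_n,
        qc_quarter_rule=config.qc_quarter_rule,
        aggregate=config.aggregate,
        **config.feature_overrides,
    ).fit()

    tables = []
    for path in config.inputs:
        image = read_segmented_image(path, class_map=config.class_map)
        tables.append(extractor.transform_one(image))
        if config.labels_out is not None:
            binary, _ = extractor._coerce_binary(image, 0)
            label_map = label_regions(binary)
            image_io.write_label_map_png(label_map.labels, config.labels_out)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["image_id", "region_label", *FEATURE_NAMES]
    )
    if config.aggregate and not table.empty:
        rows = []
        for image_id, group in table.groupby("image_id", sort=False):
            row = aggregate_slide(group)
            row["image_id"] = image_id
            rows.append(row)
        agg = pd.DataFrame(rows).loc[:, ["image_id", *FEATURE_NAMES, "n_regions"]]
        agg.to_csv(config.out, index=False)
    else:
        image_io.write_feature_table(table, config.out)
    return table
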
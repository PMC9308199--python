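"""Deterministic analytic-shape fixtures.

Every primitive is rasterized by testing pixel centers against an analytic
inequality (no anti-aliasing), so measured areas obey exact discretization
bounds and the same parameters always produce byte-identical images.  Scenes
composite primitives in painter's order into category codes, emulating
multi-class segmentation maps where holes inside the tissue carry a
different class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely

from .image_io import BinaryImage, SegmentedImage

__all__ = ["ShapeSpec", "SceneSpec", "make_primitive", "make_scene", "random_scene"]

_KINDS = {"disk", "annulus", "rectangle", "ellipse", "star"}


@dataclass(frozen=True)
class ShapeSpec:
    """One primitive: kind, center position, size parameters, rotation.

    Size parameters by kind (pixels):
      disk: radius; annulus: outer, inner; rectangle: width, height (width is
      the side along the rotation direction); ellipse: a, b (semi-axes);
      star: outer, inner[, n_points=5].
    ``rotation`` is degrees, counterclockwise in the (col, -row) frame.
    """

    kind: str
    center: tuple[float, float]  # (row, col)
    params: tuple[float, ...]
    rotation: float = 0.0
    category: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if min(self.params[:2] if len(self.params) > 1 else self.params) < 1.5:
            raise ValueError("primitive sizes must be >= 3 px across")


@dataclass(frozen=True)
class SceneSpec:
    """Canvas size plus primitives composited in painter's order."""

    shape: tuple[int, int]  # (rows, cols)
    primitives: tuple[ShapeSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shape": list(self.shape),
            "seed": self.seed,
            "primitives": [
                {"kind": p.kind, "center": list(p.center), "params": list(p.params),
                 "rotation": p.rotation, "category": p.category}
                for p in self.primitives
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneSpec":
        payload = json.loads(Path(path).read_text())
        prims = tuple(
            ShapeSpec(kind=p["kind"], center=tuple(p["center"]),
                      params=tuple(p["params"]), rotation=p.get("rotation", 0.0),
                      category=p.get("category", 1))
            for p in payload["primitives"]
        )
        return cls(shape=tuple(payload["shape"]), primitives=prims,
                   seed=payload.get("seed", 0))


def _pixel_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return rows.astype(float), cols.astype(float)


def _rotate(dr: np.ndarray, dc: np.ndarray, degrees: float):
    """Coordinates in the shape's own frame: u along the rotated +col axis,
    v along the rotated -row axis (counterclockwise rotation in (col, -row))."""
    th = math.radians(degrees)
    x, y = dc, -dr
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    return u, v


def _star_polygon(spec: ShapeSpec) -> shapely.Polygon:
    outer, inner = spec.params[0], spec.params[1]
    n_points = int(spec.params[2]) if len(spec.params) > 2 else 5
    cr, cc = spec.center
    th0 = math.radians(spec.rotation)
    pts = []
    for i in range(2 * n_points):
        r = outer if i % 2 == 0 else inner
        # angle measured in (col, -row); vertex 0 points "up" (decreasing row)
        phi = th0 + math.pi / 2 + i * math.pi / n_points
        pts.append((cc + r * math.cos(phi), -(cr) + r * math.sin(phi)))
    # polygon lives in (x, y) = (col, -row)
    return shapely.Polygon(pts)


def _rasterize(spec: ShapeSpec, canvas: tuple[int, int]) -> np.ndarray:
    rows, cols = _pixel_grid(canvas)
    cr, cc = spec.center
    dr, dc = rows - cr, cols - cc
    if spec.kind == "disk":
        (r,) = spec.params[:1]
        inside = dr**2 + dc**2 <= r**2
    elif spec.kind == "annulus":
        outer, inner = spec.params[:2]
        if inner >= outer:
            raise ValueError("annulus inner radius must be < outer radius")
        rho2 = dr**2 + dc**2
        inside = (rho2 <= outer**2) & (rho2 > inner**2)
    elif spec.kind == "ellipse":
        a, b = spec.params[:2]
        u, v = _rotate(dr, dc, spec.rotation)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    elif spec.kind == "rectangle":
        w, h = spec.params[:2]
        u, v = _rotate(dr, dc, spec.rotation)
        inside = (np.abs(u) <= w / 2.0) & (np.abs(v) <= h / 2.0)
    else:  # star
        poly = _star_polygon(spec)
        pts = shapely.points(np.stack([cols.ravel(), -rows.ravel()], axis=1))
        shapely.prepare(poly)
        inside = shapely.covers(poly, pts).reshape(canvas)
    return inside


def _check_fits(inside: np.ndarray) -> None:
    # a primitive touching the canvas border would be clipped, breaking the
    # analytic area oracle
    if inside[0, :].any() or inside[-1, :].any() or inside[:, 0].any() or inside[:, -1].any():
        raise ValueError("primitive touches or exceeds the canvas border")


def make_primitive(
    kind: str,
    params: Sequence[float],
    canvas: tuple[int, int],
    center: tuple[float, float] | None = None,
    rotation: float = 0.0,
) -> BinaryImage:
    """Rasterize one analytic primitive onto an otherwise empty canvas.

    The shape must fit strictly inside the canvas (no border contact).
    """
    if center is None:
        center = ((canvas[0] - 1) / 2.0, (canvas[1] - 1) / 2.0)
    spec = ShapeSpec(kind=kind, center=center, params=tuple(params), rotation=rotation)
    inside = _rasterize(spec, canvas)
    _check_fits(inside)
    return BinaryImage(pixels=inside.astype(np.uint8))


def make_scene(spec: SceneSpec) -> SegmentedImage:
    """Composite the primitives in painter's order into a category matrix.

    Later primitives overwrite earlier ones where they overlap (including
    category-0 primitives, which punch holes).
    """
    canvas = np.zeros(spec.shape, dtype=np.int64)
    for prim in spec.primitives:
        inside = _rasterize(prim, spec.shape)
        _check_fits(inside)
        canvas[inside] = prim.category
    return SegmentedImage(pixels=canvas, source_id=f"scene-seed{spec.seed}")


def random_scene(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    n_disks: int = 3,
    radius_range: tuple[float, float] = (8.0, 24.0),
    n_classes: int = 2,
) -> SceneSpec:
    """A reproducible scene of non-overlapping random disks.

    Rejection-samples centers so disks neither overlap nor touch the border;
    the same seed always yields the same spec.
    """
    rng = np.random.default_rng(seed)
    placed: list[ShapeSpec] = []
    attempts = 0
    while len(placed) < n_disks and attempts < 10_000:
        attempts += 1
        r = float(rng.uniform(*radius_range))
        cr = float(rng.uniform(r + 2, shape[0] - r - 3))
        cc = float(rng.uniform(r + 2, shape[1] - r - 3))
        if any(
            math.hypot(cr - p.center[0], cc - p.center[1]) < r + p.params[0] + 3
            for p in placed
        ):
            continue
        category = 1 if n_classes == 2 else int(rng.integers(1, n_classes))
        placed.append(ShapeSpec(kind="disk", center=(cr, cc), params=(r,),
                                category=category))
    if len(placed) < n_disks:
        raise RuntimeError("could not place all disks; reduce n_disks or radii")
    return SceneSpec(shape=shape, primitives=tuple(placed), seed=seed)
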
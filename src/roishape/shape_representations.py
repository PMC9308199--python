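"""Per-region shape representations.

From a labelled region we build six representations: the cropped binary mask,
the closed polygonal chain of boundary pixel centers, the Freeman chain code,
the curvature (turning-angle) code, the normalized radial lengths, and the
convex hull with its minimum-area bounding box.

Conventions
-----------
* Coordinates are (row, col), 0-based, origin top-left, rows increasing
  downward.  Orientation-sensitive quantities (counterclockwise order,
  turning angles, box angle) are measured in the right-handed frame
  (x, y) = (col, -row), so a positively-oriented simple boundary has turning
  angles summing to +2*pi.
* The boundary is the chain of pixel centers produced by Moore-neighbour
  tracing (not the inter-pixel "crack" boundary): chain codes and radial
  lengths are classically defined on pixel centers.
* Freeman directions, as (dcol, drow):
  0=(+1,0) 1=(+1,-1) 2=(0,-1) 3=(-1,-1) 4=(-1,0) 5=(-1,+1) 6=(0,+1) 7=(+1,+1)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .roi_labelling import RegionLabelMap

__all__ = [
    "RegionMask",
    "PolygonalChain",
    "ChainCode",
    "CurvatureCode",
    "RadialLengths",
    "ConvexHull",
    "BoundingBox",
    "ShapeObject",
    "DegenerateShapeError",
    "extract_region_mask",
    "trace_boundary",
    "chain_code",
    "curvature_chain_code",
    "radial_lengths",
    "convex_hull",
    "min_bounding_box",
    "build_shape_object",
    "shoelace_area",
    "FREEMAN_STEPS",
]

# Freeman direction -> (drow, dcol); index order is counterclockwise in (col, -row).
FREEMAN_STEPS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)
_STEP_TO_CODE = {step: code for code, step in enumerate(FREEMAN_STEPS)}

#: Regions below this pixel count carry the degenerate flag: curvature, hull
#: and radial descriptors are meaningless on a handful of pixels.
DEGENERATE_AREA_THRESHOLD = 5


class DegenerateShapeError(ValueError):
    """Raised when an operation needs a non-degenerate boundary or hull."""


@dataclass(frozen=True)
class RegionMask:
    """Tightly cropped binary mask of one region.

    ``offset`` locates the crop's top-left corner in the parent image.
    """

    mask: np.ndarray
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        m = np.ascontiguousarray(self.mask, dtype=np.uint8)
        if m.ndim != 2 or m.sum() == 0:
            raise ValueError("mask must be 2-D with at least one foreground pixel")
        rows = m.any(axis=1)
        cols = m.any(axis=0)
        if not (rows[0] and rows[-1] and cols[0] and cols[-1]):
            raise ValueError("mask crop must be tight")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PolygonalChain:
    """Closed chain of boundary pixel centers in parent-image coordinates."""

    vertices: np.ndarray  # (n, 2) of (row, col)
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return 0 if self.degenerate or self.n < 2 else self.n

    def edge_lengths(self) -> np.ndarray:
        """Cyclic edge lengths: 1 per cardinal step, sqrt(2) per diagonal."""
        if self.n_edges == 0:
            return np.empty(0)
        diffs = np.roll(self.vertices, -1, axis=0) - self.vertices
        return np.hypot(diffs[:, 0], diffs[:, 1])


@dataclass(frozen=True)
class ChainCode:
    """Freeman 8-direction code, one entry per chain edge (cyclic)."""

    codes: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class CurvatureCode:
    """Turning angles (radians, each in (-pi, pi]) between consecutive edges."""

    angles: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class RadialLengths:
    """Centroid-to-vertex distances, raw and normalized by their maximum."""

    centroid: tuple[float, float]
    raw: np.ndarray
    normalized: np.ndarray


@dataclass(frozen=True)
class ConvexHull:
    """Convex hull of the chain vertices, counterclockwise in (col, -row)."""

    vertices: np.ndarray  # (h, 2) of (row, col)
    hull_area: float
    hull_perimeter: float


@dataclass(frozen=True)
class BoundingBox:
    """Minimum-area enclosing rectangle of the hull.

    Side lengths are pixel-footprint extents: the caliper span of the pixel
    centers plus one, so an axis-aligned w-by-h block reports exactly w and h.
    ``angle`` is the orientation of the long side, degrees in [0, 180),
    measured counterclockwise from the +col axis in the (col, -row) frame.
    """

    length: float
    width: float
    angle: float

    @property
    def box_area(self) -> float:
        return self.length * self.width


@dataclass(frozen=True)
class ShapeObject:
    """All representations of one region, derived consistently."""

    label: int
    mask: RegionMask
    chain: PolygonalChain
    chain_code: ChainCode
    curvature: CurvatureCode
    radial: RadialLengths | None
    hull: ConvexHull | None
    bbox: BoundingBox | None
    degenerate: bool = field(default=False)


def extract_region_mask(label_map: RegionLabelMap, label: int) -> RegionMask:
    """Tightly crop the pixels of one labelled region."""
    if not 1 <= label <= label_map.k:
        raise ValueError(f"label {label} out of range 1..{label_map.k}")
    where = label_map.labels == label
    rows = np.flatnonzero(where.any(axis=1))
    cols = np.flatnonzero(where.any(axis=0))
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    return RegionMask(
        mask=where[r0 : r1 + 1, c0 : c1 + 1].astype(np.uint8),
        offset=(int(r0), int(c0)),
    )


def _moore_next(mask: np.ndarray, p: tuple[int, int], back_dir: int):
    """From pixel p, scan the Moore neighbourhood counterclockwise starting
    just after the backtrack direction; return (next pixel, its backtrack dir).
    """
    nrows, ncols = mask.shape
    for i in range(1, 9):
        d = (back_dir + i) % 8
        dr, dc = FREEMAN_STEPS[d]
        r, c = p[0] + dr, p[1] + dc
        if 0 <= r < nrows and 0 <= c < ncols and mask[r, c]:
            # backtrack of the new pixel: the previously examined (background)
            # neighbour, expressed as a direction from the new pixel
            pd = (back_dir + i - 1) % 8
            pdr, pdc = FREEMAN_STEPS[pd]
            br, bc = p[0] + pdr, p[1] + pdc
            return (r, c), _STEP_TO_CODE[(br - r, bc - c)]
    return None, None


def trace_boundary(region: RegionMask) -> PolygonalChain:
    """Trace the outer boundary by Moore-neighbour tracing.

    Starts at the topmost-leftmost foreground pixel, runs counterclockwise in
    the (col, -row) frame, and terminates with Jacob's stopping criterion
    (re-entering the start pixel about to repeat the initial move).  Thin
    regions legitimately revisit pixels; a single-pixel region yields a
    degenerate one-vertex chain.
    """
    mask = region.mask
    fg = np.argwhere(mask)
    start = (int(fg[0, 0]), int(fg[0, 1]))  # argwhere is raster-ordered

    if region.area == 1:
        verts = np.array([start]) + np.array(region.offset)
        return PolygonalChain(vertices=verts, degenerate=True)

    # Entered the start pixel "from the west" during the raster scan.
    back_dir = 4
    first, first_back = _moore_next(mask, start, back_dir)
    if first is None:  # isolated pixel among others is impossible here, but safe
        verts = np.array([start]) + np.array(region.offset)
        return PolygonalChain(vertices=verts, degenerate=True)

    chain: list[tuple[int, int]] = [start]
    p, bd = first, first_back
    # generous bound: each pixel can be visited at most 4 times on a boundary
    for _ in range(4 * mask.size + 8):
        if p == start:
            nxt, _ = _moore_next(mask, p, bd)
            if nxt == first:  # Jacob's criterion: about to repeat the first move
                break
        chain.append(p)
        p, bd = _moore_next(mask, p, bd)
    verts = np.asarray(chain, dtype=np.int64) + np.asarray(region.offset, dtype=np.int64)
    return PolygonalChain(vertices=verts, degenerate=False)


def chain_code(chain: PolygonalChain) -> ChainCode:
    """Freeman chain code of the closed chain, one code per edge."""
    if chain.n_edges == 0:
        return ChainCode(codes=np.empty(0, dtype=np.int8), degenerate=True)
    diffs = np.roll(chain.vertices, -1, axis=0) - chain.vertices
    codes = np.array([_STEP_TO_CODE[(int(dr), int(dc))] for dr, dc in diffs],
                     dtype=np.int8)
    return ChainCode(codes=codes)


def curvature_chain_code(code: ChainCode) -> CurvatureCode:
    """Turning angles between consecutive Freeman codes, cyclically.

    angle_i = wrap(code_{i+1} - code_i) * pi/4, wrapped into (-pi, pi]; for a
    simple closed boundary the angles sum to +2*pi (counterclockwise trace).
    """
    if code.degenerate or len(code.codes) < 2:
        return CurvatureCode(angles=np.empty(0), degenerate=True)
    c = code.codes.astype(np.int64)
    diff = (np.roll(c, -1) - c) % 8
    diff = np.where(diff > 4, diff - 8, diff)  # -> {-3..4}, i.e. (-pi, pi]
    return CurvatureCode(angles=diff * (math.pi / 4.0))


def radial_lengths(chain: PolygonalChain, region: RegionMask) -> RadialLengths:
    """Distances from the region centroid to each chain vertex, in chain order.

    The centroid is the mean coordinate of all foreground pixels of the mask
    (not of the boundary vertices), which is robust to boundary revisits on
    thin regions.  Normalization divides by the maximum distance.
    """
    if chain.degenerate:
        raise DegenerateShapeError("radial lengths need a non-degenerate chain")
    fg = np.argwhere(region.mask).astype(float)
    centroid = fg.mean(axis=0) + np.asarray(region.offset, dtype=float)
    d = chain.vertices.astype(float) - centroid
    raw = np.hypot(d[:, 0], d[:, 1])
    rmax = raw.max()
    if rmax == 0:
        raise DegenerateShapeError("all chain vertices coincide with the centroid")
    return RadialLengths(centroid=(float(centroid[0]), float(centroid[1])),
                         raw=raw, normalized=raw / rmax)


def _cross(o, a, b) -> int:
    """2-D cross product (OA x OB) in the (col, -row) frame, integer-exact."""
    return (a[1] - o[1]) * -(b[0] - o[0]) - -(a[0] - o[0]) * (b[1] - o[1])


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area in the (col, -row) frame; positive = counterclockwise."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 1], -v[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def convex_hull(chain: PolygonalChain) -> ConvexHull:
    """Andrew monotone-chain convex hull of the chain vertices.

    Vertices are returned counterclockwise in the (col, -row) frame; collinear
    intermediate points are dropped.  Fewer than three distinct non-collinear
    vertices raise :class:`DegenerateShapeError`.
    """
    pts = sorted({(int(r), int(c)) for r, c in chain.vertices},
                 key=lambda p: (p[1], -p[0]))  # sort by x, then y in (col,-row)
    if len(pts) < 3:
        raise DegenerateShapeError("convex hull needs >= 3 distinct vertices")

    def half(points):
        out: list[tuple[int, int]] = []
        for p in points:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(pts[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        raise DegenerateShapeError("chain vertices are collinear")
    verts = np.asarray(hull, dtype=np.int64)
    area = shoelace_area(verts)
    edges = np.roll(verts, -1, axis=0) - verts
    perim = float(np.hypot(edges[:, 0], edges[:, 1]).sum())
    return ConvexHull(vertices=verts, hull_area=abs(area), hull_perimeter=perim)


def min_bounding_box(hull: ConvexHull) -> BoundingBox:
    """Minimum-area enclosing rectangle by rotating calipers.

    One side of the optimal rectangle is collinear with a hull edge, so only
    hull-edge orientations are examined.  Side lengths are the caliper spans
    of the pixel centers plus one (pixel footprint); the minimized quantity is
    that footprint area.  Area ties are broken by the smaller angle; the
    reported angle is that of the long side, degrees in [0, 180).
    """
    # center on the first vertex (integer offsets) so the caliper projections,
    # and hence the box, are exactly translation invariant
    v = (hull.vertices - hull.vertices[0]).astype(float)
    x, y = v[:, 1], -v[:, 0]
    edges = np.stack([np.roll(x, -1) - x, np.roll(y, -1) - y], axis=1)
    norms = np.hypot(edges[:, 0], edges[:, 1])
    best: tuple[float, float, float, float] | None = None  # (area, angle, L, W)
    for (ex, ey), n in zip(edges, norms):
        if n == 0:
            continue
        ux, uy = ex / n, ey / n  # edge direction and its normal
        proj_u = x * ux + y * uy
        proj_w = -x * uy + y * ux
        du = proj_u.max() - proj_u.min() + 1.0
        dw = proj_w.max() - proj_w.min() + 1.0
        area = du * dw
        if du >= dw:
            ang = math.degrees(math.atan2(uy, ux))
        else:
            ang = math.degrees(math.atan2(ux, -uy))  # normal direction
        ang %= 180.0
        cand = (area, ang, max(du, dw), min(du, dw))
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            best = cand
    if best is None:
        raise DegenerateShapeError("degenerate hull")
    _, angle, length, width = best
    return BoundingBox(length=float(length), width=float(width), angle=float(angle))


def build_shape_object(
    label_map: RegionLabelMap,
    label: int,
    degenerate_area_threshold: int = DEGENERATE_AREA_THRESHOLD,
) -> ShapeObject:
    """Build every representation for one region and bundle them.

    Regions under ``degenerate_area_threshold`` pixels are flagged degenerate:
    hull, box and radial descriptors are suppressed (``None``) and downstream
    boundary/geometric features are reported missing.
    """
    region = extract_region_mask(label_map, label)
    chain = trace_boundary(region)
    code = chain_code(chain)
    curv = curvature_chain_code(code)
    degenerate = chain.degenerate or region.area < degenerate_area_threshold

    radial = hull = bbox = None
    if not degenerate:
        try:
            radial = radial_lengths(chain, region)
            hull = convex_hull(chain)
            bbox = min_bounding_box(hull)
        except DegenerateShapeError:
            degenerate, radial, hull, bbox = True, None, None, None
    return ShapeObject(label=label, mask=region, chain=chain, chain_code=code,
                       curvature=curv, radial=radial, hull=hull, bbox=bbox,
                       degenerate=degenerate)
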
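"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: flood fill
by explicit stack traversal, hole counting by border-reachability, and the
minimum bounding box by a dense angle sweep.  They are slow but obviously
correct, and every geometric claim in the suite is checked against them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from roishape import build_shape_object, extract_all, label_regions
from roishape.synthetic_shapes import make_primitive


# ---------------------------------------------------------------------------
# independent oracles


def oracle_flood_fill(mask: np.ndarray) -> list[frozenset]:
    """4-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask)
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, pixels = [(r0, c0)], set()
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                pixels.add((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            components.append(frozenset(pixels))
    return components


def oracle_hole_count(mask: np.ndarray) -> int:
    """Holes = 8-connected background components not reachable from the border."""
    mask = np.asarray(mask)
    nr, nc = mask.shape
    seen = np.zeros((nr, nc), dtype=bool)

    def flood(r0, c0):
        stack = [(r0, c0)]
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nr and 0 <= cc < nc
                            and not mask[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))

    for r in range(nr):
        for c in (0, nc - 1):
            if not mask[r, c] and not seen[r, c]:
                flood(r, c)
    for c in range(nc):
        for r in (0, nr - 1):
            if not mask[r, c] and not seen[r, c]:
                flood(r, c)

    holes = 0
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c] and not seen[r, c]:
                flood(r, c)
                holes += 1
    return holes


def oracle_min_box(points: np.ndarray, step_deg: float = 0.1):
    """Minimum pixel-footprint box by dense angle sweep.

    ``points`` are (row, col) pixel centers; extents at each angle are the
    caliper span plus one (the same footprint convention the library uses).
    Returns (area, angle_of_long_side_deg).
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 1], -pts[:, 0]
    best = (math.inf, 0.0)
    for ang in np.arange(0.0, 90.0, step_deg):
        th = math.radians(ang)
        u = x * math.cos(th) + y * math.sin(th)
        w = -x * math.sin(th) + y * math.cos(th)
        du = u.max() - u.min() + 1.0
        dw = w.max() - w.min() + 1.0
        area = du * dw
        if area < best[0]:
            long_ang = ang if du >= dw else ang + 90.0
            best = (area, long_ang % 180.0)
    return best


# ---------------------------------------------------------------------------
# analytic-shape fixtures (session-scoped: each is built once per run)


def shape_of(image) -> "object":
    label_map = label_regions(image)
    assert label_map.k >= 1
    return build_shape_object(label_map, 1)


@pytest.fixture(scope="session")
def disk100():
    return shape_of(make_primitive("disk", (100,), (256, 256)))


@pytest.fixture(scope="session")
def disk100_features(disk100):
    return extract_all(disk100)

@pytest.fixture(scope="session")
def star5():
    """Five-point star, outer radius 100, inner radius 40."""
    return shape_of(make_primitive("star", (100, 40), (256, 256)))


@pytest.fixture(scope="session")
def star5_features(star5):
    return extract_all(star5)


@pytest.fixture(scope="session")
def rect40x10():
    return shape_of(make_primitive("rectangle", (40, 10), (64, 64)))


@pytest.fixture(scope="session")
def ellipse50x25():
    return shape_of(make_primitive("ellipse", (50, 25), (160, 160)))


@pytest.fixture(scope="session")
def annulus50_20():
    return shape_of(make_primitive("annulus", (50, 20), (128, 128)))
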
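"""Boundary tracing, chain codes, curvature, radial lengths, hull and box."""

import math

import numpy as np
import pytest
import shapely

from roishape import (
    BinaryImage,
    build_shape_object,
    chain_code,
    convex_hull,
    curvature_chain_code,
    extract_region_mask,
    label_regions,
    min_bounding_box,
    radial_lengths,
    trace_boundary,
)
from roishape.shape_representations import (
    ChainCode,
    DegenerateShapeError,
    PolygonalChain,
    shoelace_area,
)
from roishape.synthetic_shapes import make_primitive

from conftest import oracle_min_box, shape_of


def _shape_from_array(arr):
    label_map = label_regions(BinaryImage(pixels=np.asarray(arr, dtype=np.uint8)))
    return label_map


class TestRegionMask:
    def test_tight_crop_and_offset(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[2:5, 1:4] = [[1, 0, 0], [1, 0, 0], [1, 1, 1]]  # L-shape
        label_map = _shape_from_array(img)
        region = extract_region_mask(label_map, 1)
        assert region.offset == (2, 1)
        assert region.mask.shape == (3, 3)
        assert region.area == 5

    def test_single_pixel(self):
        img = np.zeros((8, 9), dtype=np.uint8)
        img[5, 7] = 1
        region = extract_region_mask(_shape_from_array(img), 1)
        assert region.mask.shape == (1, 1)
        assert region.offset == (5, 7)
        assert region.area == 1

    def test_label_out_of_range(self):
        img = np.ones((2, 2), dtype=np.uint8)
        label_map = _shape_from_array(img)
        with pytest.raises(ValueError):
            extract_region_mask(label_map, label_map.k + 1)


class TestTraceBoundary:
    def test_2x2_block_traces_all_four_pixels_counterclockwise(self):
        """Hand-enumerated Moore trace of a 2x2 block at rows/cols 1..2."""
        img = np.zeros((4, 4), dtype=np.uint8)
        img[1:3, 1:3] = 1
        chain = trace_boundary(extract_region_mask(_shape_from_array(img), 1))
        assert chain.vertices.tolist() == [[1, 1], [2, 1], [2, 2], [1, 2]]
        assert not chain.degenerate

    def test_1x3_bar_revisits_interiorless_pixels(self):
        """Hand-enumerated: the bar's boundary walks out and back, 4 edges."""
        img = np.zeros((3, 5), dtype=np.uint8)
        img[1, 1:4] = 1
        chain = trace_boundary(extract_region_mask(_shape_from_array(img), 1))
        assert chain.vertices.tolist() == [[1, 1], [1, 2], [1, 3], [1, 2]]
        assert chain.n_edges == 4

    def test_single_pixel_is_degenerate(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        img[1, 1] = 1
        chain = trace_boundary(extract_region_mask(_shape_from_array(img), 1))
        assert chain.degenerate
        assert chain.n == 1
        assert chain.n_edges == 0

    def test_every_vertex_touches_background_or_border(self, star5):
        """Chain vertices are boundary pixels: a background 4-neighbour exists."""
        mask = star5.mask.mask
        off = np.array(star5.mask.offset)
        padded = np.pad(mask, 1)
        for r, c in star5.chain.vertices:
            pr, pc = r - off[0] + 1, c - off[1] + 1
            neighbours = [padded[pr - 1, pc], padded[pr + 1, pc],
                          padded[pr, pc - 1], padded[pr, pc + 1]]
            assert padded[pr, pc] == 1 and min(neighbours) == 0

    def test_consecutive_vertices_are_8_adjacent(self, star5):
        diffs = np.abs(np.roll(star5.chain.vertices, -1, axis=0) - star5.chain.vertices)
        assert diffs.max() == 1


class TestChainCode:
    @pytest.mark.parametrize(
        "step,code",
        [((0, 1), 0), ((-1, 1), 1), ((-1, 0), 2), ((-1, -1), 3),
         ((0, -1), 4), ((1, -1), 5), ((1, 0), 6), ((1, 1), 7)],
    )
    def test_all_eight_directions(self, step, code):
        """(drow, dcol) steps map to the Freeman convention in (dcol, drow)."""
        verts = np.array([[5, 5], [5 + step[0], 5 + step[1]]])
        codes = chain_code(PolygonalChain(vertices=verts)).codes
        assert codes[0] == code

    def test_2x2_block_has_one_code_per_cardinal_direction(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[1:3, 1:3] = 1
        chain = trace_boundary(extract_region_mask(_shape_from_array(img), 1))
        assert chain_code(chain).codes.tolist() == [6, 0, 2, 4]

    def test_degenerate_chain_yields_empty_code(self):
        chain = PolygonalChain(vertices=np.array([[0, 0]]), degenerate=True)
        code = chain_code(chain)
        assert code.degenerate and len(code.codes) == 0


class TestCurvature:
    def test_straight_run_has_zero_turning(self):
        angles = curvature_chain_code(ChainCode(codes=np.array([0, 0, 0, 4, 4, 4]))).angles
        assert angles[0] == 0.0 and angles[1] == 0.0

    def test_left_turn_by_two_codes_is_plus_half_pi(self):
        angles = curvature_chain_code(ChainCode(codes=np.array([0, 2]))).angles
        assert angles[0] == pytest.approx(math.pi / 2)

    def test_output_is_cyclic_and_same_length(self):
        code = ChainCode(codes=np.array([6, 0, 2, 4]))
        angles = curvature_chain_code(code).angles
        assert len(angles) == 4

    @pytest.mark.parametrize("kind,params,canvas", [
        ("disk", (40,), (128, 128)),
        ("star", (50, 20), (128, 128)),
        ("rectangle", (30, 12), (64, 64)),
        ("ellipse", (40, 18), (128, 128)),
    ])
    def test_turning_angles_of_simple_boundaries_sum_to_plus_2pi(
        self, kind, params, canvas
    ):
        shape = shape_of(make_primitive(kind, params, canvas))
        assert shape.curvature.angles.sum() == pytest.approx(2 * math.pi, abs=1e-9)


class TestRadialLengths:
    def test_disk_normalized_lengths_near_one(self, disk100):
        assert disk100.radial.normalized.min() >= 0.95
        assert disk100.radial.normalized.max() == 1.0

    def test_square_min_normalized_is_inverse_sqrt2(self):
        shape = shape_of(make_primitive("rectangle", (101, 101), (128, 128)))
        assert shape.radial.normalized.min() == pytest.approx(1 / math.sqrt(2), abs=0.02)

    @pytest.mark.parametrize("kind,params", [("disk", (30,)), ("star", (50, 20))])
    def test_max_normalized_is_one_and_lengths_match_chain(self, kind, params):
        shape = shape_of(make_primitive(kind, params, (128, 128)))
        assert shape.radial.normalized.max() == 1.0
        assert len(shape.radial.raw) == shape.chain.n

    def test_degenerate_chain_is_an_error(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        img[1, 1] = 1
        label_map = _shape_from_array(img)
        region = extract_region_mask(label_map, 1)
        with pytest.raises(DegenerateShapeError):
            radial_lengths(trace_boundary(region), region)


class TestConvexHull:
    def test_hull_dominates_chain_area_with_equality_for_true_polygons(
        self, disk100, rect40x10
    ):
        """The hull encloses the chain polygon; for a shape whose chain is
        already convex (an axis-aligned rectangle) the two areas coincide.
        A digitized disk's chain is a staircase, so its hull is strictly
        larger."""
        assert disk100.hull.hull_area >= abs(shoelace_area(disk100.chain.vertices))
        rect_enclosed = abs(shoelace_area(rect40x10.chain.vertices))
        assert rect40x10.hull.hull_area == pytest.approx(rect_enclosed, abs=1e-9)

    def test_star_hull_has_five_tip_clusters_and_exceeds_chain_area(self, star5):
        assert star5.hull.hull_area > abs(shoelace_area(star5.chain.vertices))
        # hull vertices must be a subset of chain vertices
        chain_set = {tuple(v) for v in star5.chain.vertices.tolist()}
        assert all(tuple(v) in chain_set for v in star5.hull.vertices.tolist())

    def test_hull_matches_shapely_oracle(self, star5):
        pts = shapely.MultiPoint(
            [(c, -r) for r, c in star5.chain.vertices.tolist()]
        )
        expected = pts.convex_hull.area
        assert star5.hull.hull_area == pytest.approx(expected, rel=1e-12)
        assert star5.hull.hull_perimeter == pytest.approx(pts.convex_hull.length, rel=1e-12)

    def test_hull_is_convex_and_counterclockwise(self, star5):
        v = star5.hull.vertices.astype(float)
        x, y = v[:, 1], -v[:, 0]
        cross = ((np.roll(x, -1) - x) * (np.roll(y, -2) - np.roll(y, -1))
                 - (np.roll(y, -1) - y) * (np.roll(x, -2) - np.roll(x, -1)))
        assert (cross > 0).all()

    def test_collinear_bar_is_degenerate(self):
        img = np.zeros((3, 5), dtype=np.uint8)
        img[1, 1:4] = 1
        chain = trace_boundary(extract_region_mask(_shape_from_array(img), 1))
        with pytest.raises(DegenerateShapeError):
            convex_hull(chain)


class TestMinBoundingBox:
    def test_axis_aligned_rectangle_self_encloses(self, rect40x10):
        bbox = rect40x10.bbox
        assert bbox.box_area == pytest.approx(400, abs=0.5)
        assert bbox.angle == pytest.approx(0, abs=1e-6) or bbox.angle == pytest.approx(
            180, abs=1e-6
        )
        assert bbox.length == pytest.approx(40, abs=0.5)
        assert bbox.width == pytest.approx(10, abs=0.5)

    def test_rotated_rectangle_angle_recovered_within_2_degrees(self):
        shape = shape_of(make_primitive("rectangle", (60, 20), (128, 128), rotation=30))
        assert shape.bbox.angle == pytest.approx(30, abs=2.0)
        _, sweep_angle = oracle_min_box(shape.hull.vertices)
        assert abs(shape.bbox.angle - sweep_angle) <= 2.0

    @pytest.mark.parametrize("kind,params,canvas,rot", [
        ("disk", (50,), (128, 128), 0),
        ("star", (50, 20), (128, 128), 10),
        ("rectangle", (40, 10), (64, 64), 30),
        ("ellipse", (40, 18), (128, 128), 25),
    ])
    def test_calipers_match_brute_force_sweep_within_half_percent(
        self, kind, params, canvas, rot
    ):
        shape = shape_of(make_primitive(kind, params, canvas, rotation=rot))
        sweep_area, _ = oracle_min_box(shape.hull.vertices)
        assert shape.bbox.box_area <= sweep_area + 1e-9
        assert shape.bbox.box_area == pytest.approx(sweep_area, rel=0.005)

    def test_disk_box_area_close_to_diameter_squared(self, disk100):
        assert disk100.bbox.box_area == pytest.approx(200**2, rel=0.05)

    def test_box_encloses_hull(self, star5):
        assert star5.bbox.box_area >= star5.hull.hull_area * (1 - 1e-6)
        assert star5.bbox.width <= star5.bbox.length


class TestBuildShapeObject:
    def test_all_components_populated_for_a_disk(self, disk100):
        assert not disk100.degenerate
        for part in (disk100.mask, disk100.chain, disk100.chain_code,
                     disk100.curvature, disk100.radial, disk100.hull, disk100.bbox):
            assert part is not None

    def test_tiny_region_carries_degenerate_flag(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 1
        shape = build_shape_object(_shape_from_array(img), 1)
        assert shape.degenerate
        assert shape.hull is None and shape.bbox is None and shape.radial is None


class TestEquivariance:
    def test_translation_shifts_chain_and_centroid_exactly(self):
        img = np.zeros((128, 128), dtype=np.uint8)
        base = make_primitive("star", (30, 12), (80, 80)).pixels
        img[: base.shape[0], : base.shape[1]] = base
        shifted = np.zeros_like(img)
        shifted[17:17 + base.shape[0], 23:23 + base.shape[1]] = base

        s0 = build_shape_object(_shape_from_array(img), 1)
        s1 = build_shape_object(_shape_from_array(shifted), 1)
        np.testing.assert_array_equal(
            s1.chain.vertices - [17, 23], s0.chain.vertices
        )
        np.testing.assert_array_equal(s1.chain_code.codes, s0.chain_code.codes)
        assert s1.radial.centroid[0] - 17 == pytest.approx(s0.radial.centroid[0])
        assert s1.radial.centroid[1] - 23 == pytest.approx(s0.radial.centroid[1])

    def test_quarter_turn_shifts_chain_codes_by_two_mod_eight(self):
        img = make_primitive("ellipse", (30, 12), (96, 96), rotation=10).pixels
        s0 = build_shape_object(_shape_from_array(img), 1)
        s1 = build_shape_object(_shape_from_array(np.rot90(img).copy()), 1)
        assert len(s0.chain_code.codes) == len(s1.chain_code.codes)
        expected = np.sort((s0.chain_code.codes + 2) % 8)
        assert np.array_equal(np.sort(s1.chain_code.codes), expected)
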
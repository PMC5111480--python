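import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinelv.contours import (
    Border,
    CineStudy,
    ContourTracing,
    polygon_area,
    polyline_length,
    read_contours,
    write_contours,
)
from cinelv.errors import (
    ArcIndexError,
    ContourParseError,
    DegeneratePolygonError,
    InvalidPolygonError,
    PairingError,
    StudyStructureError,
)

SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


def _regular_polygon(n, r, cx=0.0, cy=0.0):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def _pair(slice_index, phase_index, r_endo, r_epi, n=16, **kw):
    return [
        ContourTracing(slice_index, phase_index, Border.ENDOCARDIAL,
                       _regular_polygon(n, r_endo), **kw),
        ContourTracing(slice_index, phase_index, Border.EPICARDIAL,
                       _regular_polygon(n, r_epi)),
    ]


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(SQUARE) == pytest.approx(1.0)

    def test_circle_256gon(self):
        poly = _regular_polygon(256, 10.0)
        assert polygon_area(poly) == pytest.approx(math.pi * 100.0, rel=1e-3)

    def test_orientation_independent(self):
        assert polygon_area(SQUARE) == polygon_area(SQUARE[::-1])

    def test_degenerate(self):
        with pytest.raises(DegeneratePolygonError):
            polygon_area([(0, 0), (1, 1)])
        with pytest.raises(DegeneratePolygonError):
            polygon_area([(0, 0), (0, 0), (1, 1), (0, 1)])

    def test_self_intersecting_bowtie(self):
        with pytest.raises(InvalidPolygonError):
            polygon_area([(0, 0), (1, 1), (1, 0), (0, 1)])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(6, 40), st.integers(0, 10_000))
    def test_matches_fan_triangulation_on_convex_polygons(self, n, seed):
        """Shoelace area equals a fan-triangulation oracle on random convex
        polygons to 1e-9 relative."""
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(n, 2))
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]  # counter-clockwise, simple by construction
        fan = 0.0
        for i in range(1, len(verts) - 1):
            a = verts[i] - verts[0]
            b = verts[i + 1] - verts[0]
            fan += 0.5 * (a[0] * b[1] - a[1] * b[0])
        assert polygon_area(verts) == pytest.approx(abs(fan), rel=1e-9)


class TestPolylineLength:
    def test_full_perimeter(self):
        assert polyline_length(SQUARE, closed=True) == pytest.approx(4.0)

    def test_two_edges(self):
        assert polyline_length(SQUARE, (0, 3)) == pytest.approx(2.0)

    def test_empty_range(self):
        assert polyline_length(SQUARE, (2, 2)) == 0.0

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            polyline_length(SQUARE, (0, 5))
        with pytest.raises(IndexError):
            polyline_length(SQUARE, (-1, 2))

    @pytest.mark.parametrize("sub", [(0, 1), (0, 2), (1, 4), (2, 3)])
    def test_subarc_never_exceeds_perimeter(self, sub):
        full = polyline_length(SQUARE, closed=True)
        assert polyline_length(SQUARE, sub) <= full


class TestContourTracing:
    def test_arc_bounds(self):
        with pytest.raises(ArcIndexError):
            ContourTracing(0, 0, Border.ENDOCARDIAL, SQUARE, infarct_arcs=[(0, 5)])

    def test_arc_overlap(self):
        with pytest.raises(ArcIndexError):
            ContourTracing(0, 0, Border.ENDOCARDIAL, SQUARE,
                           infarct_arcs=[(0, 3), (2, 4)])

    def test_infarct_length_full_marking_is_perimeter(self):
        t = ContourTracing(0, 0, Border.ENDOCARDIAL, SQUARE, infarct_arcs=[(0, 4)])
        assert t.infarct_length() == pytest.approx(t.perimeter())

    def test_infarct_length_partial(self):
        # vertices 0..2 marked -> edges (0,1) and (1,2) of the unit square
        t = ContourTracing(0, 0, Border.ENDOCARDIAL, SQUARE, infarct_arcs=[(0, 3)])
        assert t.infarct_length() == pytest.approx(2.0)


class TestCineStudy:
    def test_missing_pair(self):
        tr = _pair(0, 0, 1.0, 2.0)[:1]
        with pytest.raises(PairingError):
            CineStudy("m1", "week1", tr)

    def test_containment_violation(self):
        tr = _pair(0, 0, 2.0, 1.0)  # endo larger than epi
        with pytest.raises(PairingError):
            CineStudy("m1", "week1", tr)

    def test_noncontiguous_slices(self):
        tr = _pair(0, 0, 1.0, 2.0) + _pair(2, 0, 1.0, 2.0)
        with pytest.raises(StudyStructureError):
            CineStudy("m1", "week1", tr)

    def test_inconsistent_phases(self):
        tr = _pair(0, 0, 1.0, 2.0) + _pair(0, 1, 1.0, 2.0) + _pair(1, 0, 1.0, 2.0)
        with pytest.raises(StudyStructureError):
            CineStudy("m1", "week1", tr)

    def test_bad_slice_thickness(self):
        with pytest.raises(StudyStructureError):
            CineStudy("m1", "week1", _pair(0, 0, 1.0, 2.0), slice_thickness=0.0)

    def test_empty_study(self):
        with pytest.raises(StudyStructureError):
            CineStudy("m1", "week1", [])


class TestContourIO:
    def test_round_trip_identity(self, small_phantom_spec, tmp_path):
        from cinelv.synthetic import generate_phantom

        study, _ = generate_phantom(small_phantom_spec)
        p = tmp_path / "c.csv"
        write_contours(study, p)
        loaded = read_contours(p)
        assert loaded.equals(study, atol=1e-6)

    def test_rewrite_byte_identical(self, small_phantom_spec, tmp_path):
        from cinelv.synthetic import generate_phantom

        study, _ = generate_phantom(small_phantom_spec)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_contours(study, p1)
        write_contours(read_contours(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_phantom_file_tracing_count(self, default_phantom, tmp_path):
        study, _ = default_phantom
        p = tmp_path / "c.csv"
        write_contours(study, p)
        loaded = read_contours(p)
        assert len(loaded.tracings) == 7 * 20 * 2

    def test_parse_error_carries_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# slice_thickness_mm=1.0\n"
            "subject_id,timepoint,slice_index,phase_index,border,vertex_index,"
            "x_mm,y_mm,infarct\n"
            "m1,week1,0,0,endo,0,0.0,0.0,0\n"
            "m1,week1,0,0,endo,1,oops,1.0,0\n"
        )
        with pytest.raises(ContourParseError, match="line 4"):
            read_contours(p)

    def test_containment_error_on_load(self, tmp_path):
        lines = [
            "# slice_thickness_mm=1.0",
            "subject_id,timepoint,slice_index,phase_index,border,vertex_index,"
            "x_mm,y_mm,infarct",
        ]
        big = _regular_polygon(8, 2.0)
        small = _regular_polygon(8, 1.0)
        for border, poly in (("endo", big), ("epi", small)):
            for vi, (x, y) in enumerate(poly):
                lines.append(f"m1,week1,0,0,{border},{vi},{x:.6f},{y:.6f},0")
        p = tmp_path / "c.csv"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(PairingError):
            read_contours(p)

    def test_infarct_arcs_survive_round_trip(self, tmp_path):
        from cinelv.synthetic import InfarctSpec, PhantomSpec, generate_phantom

        spec = PhantomSpec(n_slices=3, n_phases=4, vertices_per_contour=48,
                           cavity_length_mm=3.5,
                           infarct=InfarctSpec(theta_extent_deg=90.0))
        study, _ = generate_phantom(spec)
        p = tmp_path / "c.csv"
        write_contours(study, p)
        loaded = read_contours(p)
        for sl in study.slices:
            for b in (Border.EPICARDIAL, Border.ENDOCARDIAL):
                orig = study.get(sl, 0, b)
                got = loaded.get(sl, 0, b)
                assert np.array_equal(
                    orig.infarct_vertex_mask(), got.infarct_vertex_mask()
                )
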
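"""Shape descriptors: closed forms, raster oracle, box-counting benchmarks."""

import math

import numpy as np
import pytest

from histogate.io import CellInstance, CellType, GeometryError
from histogate.morphometry import (
    aggregate_morphology,
    eccentricity,
    fractal_dimension,
    major_axis_length,
    polygon_moments,
)

from conftest import ellipse_ring, koch_polyline, straight_segment_ring


class TestMomentDescriptors:
    def test_ellipse_closed_form(self):
        """Semi-axes (5, 3): e = sqrt(1 - 9/25) = 0.8, major axis = 10."""
        ring = ellipse_ring(5.0, 3.0)
        assert eccentricity(ring) == pytest.approx(0.8, abs=0.01)
        assert major_axis_length(ring) == pytest.approx(10.0, abs=0.1)

    def test_circle_is_round(self):
        ring = ellipse_ring(7.0, 7.0)
        assert eccentricity(ring) < 0.05
        assert major_axis_length(ring) == pytest.approx(14.0, rel=0.01)

    def test_degenerate_polygon_raises(self):
        line = np.array([[0, 0], [1, 0], [2, 0], [3, 0], [0, 0]], float)
        with pytest.raises(GeometryError):
            eccentricity(line)

    def test_matches_raster_moment_oracle(self):
        """Analytic moments agree with rasterize-then-pixel-moments at high
        resolution on random convex polygons."""
        skimage = pytest.importorskip("skimage")
        from skimage.draw import polygon as draw_polygon
        from skimage.measure import regionprops

        rng = np.random.default_rng(0)
        scale = 200.0  # raster supersampling factor
        for _ in range(5):
            # random convex polygon via convex hull of points on an ellipse
            t = np.sort(rng.uniform(0, 2 * np.pi, 16))
            a, b = rng.uniform(0.8, 1.6), rng.uniform(0.3, 0.8)
            ring = np.c_[a * np.cos(t), b * np.sin(t)]
            ring = np.vstack([ring, ring[:1]])
            img = np.zeros((int(4 * scale), int(4 * scale)), dtype=np.uint8)
            rr, cc = draw_polygon(
                (ring[:, 1] + 2.0) * scale, (ring[:, 0] + 2.0) * scale, img.shape
            )
            img[rr, cc] = 1
            props = regionprops(img)[0]
            assert eccentricity(ring) == pytest.approx(props.eccentricity, abs=1e-3)
            assert major_axis_length(ring) * scale == pytest.approx(
                props.axis_major_length, rel=0.01
            )

    @pytest.mark.parametrize("theta", [0.3, 1.1, 2.5])
    def test_rotation_translation_invariance(self, theta):
        base = ellipse_ring(6.0, 2.5, theta=0.0)
        rot = ellipse_ring(6.0, 2.5, theta=theta) + np.array([37.0, -11.0])
        assert eccentricity(rot) == pytest.approx(eccentricity(base), abs=1e-6)
        assert major_axis_length(rot) == pytest.approx(major_axis_length(base), abs=1e-6)

    def test_scale_behavior(self):
        ring = ellipse_ring(6.0, 2.5)
        k = 3.7
        assert major_axis_length(k * ring) == pytest.approx(
            k * major_axis_length(ring), rel=1e-9
        )
        assert eccentricity(k * ring) == pytest.approx(eccentricity(ring), abs=1e-3)

    def test_moment_area_matches_shoelace(self):
        ring = np.array([[0, 0], [4, 0], [4, 3], [1, 5], [0, 3], [0, 0]], float)
        area, centroid, cov = polygon_moments(ring)
        assert area == pytest.approx(16.0)
        assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestFractalDimension:
    def test_straight_segment(self):
        assert fractal_dimension(straight_segment_ring()) == pytest.approx(1.0, abs=0.05)

    def test_circle(self):
        assert fractal_dimension(ellipse_ring(10.0, 10.0, n=200)) == pytest.approx(
            1.0, abs=0.05
        )

    def test_koch_curve(self):
        """Depth-5 Koch polyline: theory log4/log3 = 1.2619."""
        assert fractal_dimension(koch_polyline(5)) == pytest.approx(
            math.log(4) / math.log(3), abs=0.08
        )

    def test_scale_invariance(self):
        ring = koch_polyline(4)
        assert fractal_dimension(7.0 * ring) == pytest.approx(
            fractal_dimension(ring), abs=0.05
        )

    def test_rotation_invariance_on_rough_cell(self):
        """Estimates for a rough nucleus-like outline move < 0.03 under rotation."""
        rng = np.random.default_rng(1)
        t = np.linspace(0, 2 * np.pi, 96, endpoint=False)
        r = 1 + 0.05 * np.sum(
            [np.cos(k * t + rng.uniform(0, 2 * np.pi)) for k in range(6, 30)], axis=0
        ) / np.sqrt(24)
        ring = np.c_[15 * r * np.cos(t), 9 * r * np.sin(t)]
        ring = np.vstack([ring, ring[:1]])
        base = fractal_dimension(ring)
        th = 0.7
        rot = ring @ np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]).T
        assert fractal_dimension(rot) == pytest.approx(base, abs=0.03)

    def test_too_few_vertices_or_scales(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        with pytest.raises(GeometryError):
            fractal_dimension(square)
        with pytest.raises(GeometryError):
            fractal_dimension(straight_segment_ring(), k_min=3, k_max=4)


def _cell(cid, ring, ctype=CellType.NEOPLASTIC):
    return CellInstance(cid, ring, ctype)


class TestAggregates:
    def test_max_and_missing_semantics(self):
        cells = [
            _cell("a", ellipse_ring(5, 3)),  # e = 0.8
            _cell("b", ellipse_ring(5, 4.9)),  # e ~ 0.2
        ]
        out = aggregate_morphology(cells)
        assert out["max_eccentricity_neoplastic"] == pytest.approx(0.8, abs=0.01)
        # no connective cells -> explicit missing, never 0
        assert math.isnan(out["mean_eccentricity_connective"])

    def test_no_neoplastic_cells_missing(self):
        cells = [_cell("a", ellipse_ring(5, 3), CellType.CONNECTIVE)]
        out = aggregate_morphology(cells)
        assert math.isnan(out["max_eccentricity_neoplastic"])
        assert out["mean_eccentricity_connective"] == pytest.approx(0.8, abs=0.01)

    def test_max_monotone_under_adding_cells(self):
        low = [_cell("a", ellipse_ring(5, 4))]
        more = low + [_cell("b", ellipse_ring(5, 2))]
        a = aggregate_morphology(low)["max_eccentricity_neoplastic"]
        b = aggregate_morphology(more)["max_eccentricity_neoplastic"]
        assert b >= a


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    scale=st.floats(min_value=0.2, max_value=25.0),
    theta=st.floats(min_value=0.0, max_value=3.14),
    a=st.floats(min_value=1.5, max_value=10.0),
    ratio=st.floats(min_value=0.2, max_value=1.0),
)
@settings(max_examples=60, deadline=None)
def test_moment_descriptor_similarity_invariance(scale, theta, a, ratio):
    """Similarity transforms scale the major axis and preserve eccentricity."""
    base = ellipse_ring(a, a * ratio)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = scale * (base @ rot.T) + np.array([11.0, -4.0])
    assert eccentricity(moved) == pytest.approx(eccentricity(base), abs=1e-6)
    assert major_axis_length(moved) == pytest.approx(scale * major_axis_length(base), rel=1e-9)
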
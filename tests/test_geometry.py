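"""Membrane reconstruction, internalization scoring, pattern registration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from qdc3dm import geometry as G


def sphere_points(n, radius, center, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return center + radius * d


@pytest.fixture(scope="module")
def sphere_surface():
    pts = sphere_points(500, 20.0, np.array([50.0, 50.0, 50.0]))
    return G.build_surface(pts, alpha_radius=50.0)


class TestBuildSurface:
    def test_sphere_is_closed_with_correct_volume(self, sphere_surface):
        assert sphere_surface.is_closed
        assert sphere_surface.volume == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.10)

    def test_huge_alpha_reduces_to_convex_hull(self):
        pts = sphere_points(200, 10.0, np.array([0.0, 0.0, 0.0]), seed=3)
        surf = G.build_surface(pts, alpha_radius=1e9)
        hull = ConvexHull(pts)
        assert len(surf.boundary_facets) == len(hull.simplices)

    def test_tetrahedron_has_four_facets(self):
        tet = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        surf = G.build_surface(tet, alpha_radius=100.0)
        assert len(surf.boundary_facets) == 4
        assert surf.is_closed

    def test_coplanar_points_rejected(self):
        pts = np.column_stack([np.random.default_rng(0).uniform(0, 1, (10, 2)), np.zeros(10)])
        with pytest.raises(ValueError, match="coplanar"):
            G.build_surface(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            G.build_surface(np.zeros((3, 3)))

    def test_anisotropic_z_scaling_applied(self):
        pts = sphere_points(300, 16.0, np.array([40.0, 40.0, 40.0]), seed=5)
        squashed = pts.copy()
        squashed[:, 2] = 40.0 + (pts[:, 2] - 40.0) / 2.0  # z stored in plane units
        surf = G.build_surface(squashed, alpha_radius=50.0, z_scale=2.0)
        assert surf.volume == pytest.approx(4 / 3 * np.pi * 16**3, rel=0.12)


class TestRelativeDistance:
    def test_spot_at_nucleus(self, sphere_surface):
        c = np.array([50.0, 50.0, 50.0])
        assert G.relative_distance(c, c, sphere_surface) == 0.0

    def test_spot_on_surface(self, sphere_surface):
        c = np.array([50.0, 50.0, 50.0])
        spot = c + np.array([19.9, 0.0, 0.0])
        rho = G.relative_distance(spot, c, sphere_surface)
        assert rho == pytest.approx(1.0, abs=0.03)

    def test_halfway_spot(self, sphere_surface):
        c = np.array([50.0, 50.0, 50.0])
        rho = G.relative_distance(c + np.array([10.0, 0, 0]), c, sphere_surface)
        assert rho == pytest.approx(0.5, abs=0.02)

    def test_radial_monotonicity(self, sphere_surface):
        c = np.array([50.0, 50.0, 50.0])
        d = np.array([1.0, 2.0, -0.5])
        d /= np.linalg.norm(d)
        rhos = [G.relative_distance(c + r * d, c, sphere_surface) for r in (2, 6, 10, 14, 18)]
        assert all(b > a for a, b in zip(rhos, rhos[1:]))

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 1000))
    def test_rho_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = sphere_points(120, 10.0, np.zeros(3), seed=seed)
        nucleus = np.zeros(3)
        spot = rng.uniform(-6, 6, 3)
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        rho1 = G.relative_distance(spot, nucleus, G.build_surface(pts, 50.0))
        rho2 = G.relative_distance(
            rot @ spot + shift, rot @ nucleus + shift, G.build_surface(pts @ rot.T + shift, 50.0)
        )
        assert rho2 == pytest.approx(rho1, abs=0.02)


class TestInternalizedFraction:
    def test_all_at_nucleus(self):
        res = G.internalized_fraction(np.zeros(5))
        assert res.fraction == 1.0

    def test_all_on_surface(self):
        res = G.internalized_fraction(np.ones(5))
        assert res.fraction == 0.0

    def test_qd_weighting(self):
        rho = np.array([0.2, 1.0])
        res = G.internalized_fraction(rho, n_qd=np.array([3.0, 1.0]))
        assert res.fraction == pytest.approx(0.75)

    def test_unresolved_spots_reported(self):
        rho = np.array([0.2, np.nan, 1.0])
        res = G.internalized_fraction(rho)
        assert res.n_unresolved == 1
        assert res.fraction == pytest.approx(0.5)

    def test_recovery_on_synthetic_cell(self, sphere_surface):
        rng = np.random.default_rng(7)
        c = np.array([50.0, 50.0, 50.0])
        n = 500
        internal = rng.random(n) < 0.6
        r = np.where(internal, rng.uniform(0.1, 0.75, n), 1.0)
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        spots = c + (r[:, None] * 20.0) * d
        rho = np.array([G.relative_distance(s, c, sphere_surface) for s in spots])
        res = G.internalized_fraction(rho)
        assert res.fraction == pytest.approx(internal.mean(), abs=0.05)
        accuracy = np.mean(res.internalized == internal)
        assert accuracy >= 0.95


class TestMembraneAccuracy:
    def test_vertices_have_zero_distance(self, sphere_surface):
        ref = sphere_surface.vertices[:100]
        out = G.membrane_accuracy(sphere_surface, ref)
        assert out["max"] < 1e-9

    def test_radial_offset_measured(self, sphere_surface):
        # the reconstructed surface is a polyhedron inscribed in the
        # sphere, so chord sag (~0.1-0.2 px at 500 points) adds to the
        # 1 px radial offset
        ref = sphere_points(200, 21.0, np.array([50.0, 50.0, 50.0]), seed=9)
        out = G.membrane_accuracy(sphere_surface, ref)
        assert out["mean"] == pytest.approx(1.0, abs=0.25)
        assert out["mean"] > 0.8

    def test_empty_reference_rejected(self, sphere_surface):
        with pytest.raises(ValueError):
            G.membrane_accuracy(sphere_surface, np.empty((0, 3)))


class TestRegistration:
    def _rect_mask(self, shape=(80, 80), horizontal=True):
        m = np.zeros(shape, bool)
        if horizontal:
            m[30:50, 20:60] = True
        else:
            m[20:60, 30:50] = True
        return m

    def test_identity_for_identical_patterns(self):
        m = self._rect_mask()
        spots = np.array([[25.0, 40.0], [55.0, 40.0]])
        out = G.register_and_project([(m, spots), (m, spots)])
        assert out["transforms"][1]["rotation"] == pytest.approx(0.0, abs=np.radians(1))
        np.testing.assert_allclose(out["pooled_xy"][:2], out["pooled_xy"][2:], atol=0.5)

    def test_quarter_turn_recovered(self):
        m1 = self._rect_mask(horizontal=True)
        m2 = self._rect_mask(horizontal=False)
        out = G.register_and_project(
            [(m1, np.array([[25.0, 40.0]])), (m2, np.array([[40.0, 25.0]]))]
        )
        assert abs(abs(np.degrees(out["transforms"][1]["rotation"])) - 90.0) < 1.0
        np.testing.assert_allclose(out["pooled_xy"][0], out["pooled_xy"][1], atol=1.0)

    def test_mirrored_layouts_give_symmetric_histogram(self):
        m = self._rect_mask()
        s1 = np.array([[27.5, 40.0]])
        s2 = np.array([[52.5, 40.0]])  # mirrored about the pattern center
        out = G.register_and_project([(m, s1), (m, s2)], bins_1d=16)
        h = out["hist1d"]
        np.testing.assert_array_equal(h, h[::-1])

    def test_low_overlap_cell_excluded(self):
        m1 = self._rect_mask()
        m2 = np.zeros((80, 80), bool)
        m2[10:16, 10:70] = True  # very different aspect: poor overlap
        with pytest.warns(UserWarning, match="excluded"):
            out = G.register_and_project(
                [(m1, np.array([[25.0, 40.0]])), (m2, np.array([[40.0, 13.0]]))]
            )
        assert out["included"] == [True, False]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            G.register_and_project([])
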
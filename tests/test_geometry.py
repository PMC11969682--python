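"""Profile generation, mirroring, domain sizing, and rasterization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from denticleflow.geometry import (DenticleParams, DenticleProfile,
                                   make_idealized_profile,
                                   make_empirical_profile, mirror_profile,
                                   build_domain, rasterize, rasterize_graded,
                                   ParameterError, DomainError,
                                   ResolutionError, MaskGrid)


class TestDenticleParams:
    @pytest.mark.parametrize("kwargs", [
        dict(n_denticles=1),
        dict(pitch=-1e-4),
        dict(denticle_height=0.0),
        dict(denticle_length=2e-4),       # base width >= pitch
        dict(tip_overhang=1.5),
        dict(perturbation_cv=-0.1),
        dict(orientation="sideways"),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            make_idealized_profile(DenticleParams(**kwargs))


class TestIdealizedProfile:
    def test_default_length_near_published_model(self, idealized_profile):
        # 20 denticles at 125 um pitch: total length within 5% of 2.5 mm
        assert idealized_profile.model_length_L == pytest.approx(2.5e-3,
                                                                 rel=0.05)

    def test_polygon_simple_and_on_floor(self, idealized_profile):
        idealized_profile.validate()
        assert idealized_profile.vertices[:, 1].min() == 0.0

    def test_two_plain_triangles_vertex_count(self):
        prof = make_idealized_profile(
            DenticleParams(n_denticles=2, tip_overhang=0.0))
        # 3 vertices per triangle plus 4 baseline corners
        assert len(prof.vertices) == 2 * 3 + 4

    def test_deterministic(self):
        a = make_idealized_profile(DenticleParams())
        b = make_idealized_profile(DenticleParams())
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_rostral_cusps_point_upstream(self, small_profile):
        # each apex must sit upstream (-x) of its denticle's base front
        assert small_profile.orientation == "rostral"
        apex = np.sort(small_profile.apex_x)
        t = small_profile.baseline_thickness
        tips = small_profile.vertices[small_profile.vertices[:, 1] > t + 1e-9]
        assert len(apex) == small_profile.n_denticles


class TestEmpiricalProfile:
    def test_seeded_reproducibility(self):
        p = DenticleParams(perturbation_cv=0.25, seed=1)
        a = make_empirical_profile(p)
        b = make_empirical_profile(p)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_seed_sensitivity(self):
        a = make_empirical_profile(DenticleParams(perturbation_cv=0.25, seed=1))
        b = make_empirical_profile(DenticleParams(perturbation_cv=0.25, seed=2))
        assert a.vertices.shape != b.vertices.shape or \
            not np.allclose(a.vertices, b.vertices)
        assert a.n_denticles == b.n_denticles

    def test_zero_cv_degenerates_to_idealized(self):
        a = make_empirical_profile(DenticleParams(perturbation_cv=0.0, seed=3))
        b = make_idealized_profile(DenticleParams())
        np.testing.assert_array_equal(a.vertices, b.vertices)
        assert a.provenance == "empirical_synthetic"

    def test_length_targets_shorter_published_model(self):
        prof = make_empirical_profile(DenticleParams(perturbation_cv=0.25,
                                                     seed=1))
        assert prof.model_length_L == pytest.approx(2.35e-3, rel=0.05)

    def test_profile_is_simple(self):
        for seed in range(5):
            prof = make_empirical_profile(
                DenticleParams(perturbation_cv=0.4, seed=seed))
            prof.validate()


class TestMirror:
    def test_involution(self, small_profile):
        back = mirror_profile(mirror_profile(small_profile))
        np.testing.assert_allclose(back.vertices, small_profile.vertices,
                                   atol=1e-12)

    def test_orientation_flips(self, small_profile):
        assert mirror_profile(small_profile).orientation == "caudal"

    def test_area_preserved(self, small_profile):
        m = mirror_profile(small_profile)
        assert m.area == pytest.approx(small_profile.area, rel=1e-12)

    def test_symmetric_denticles_self_mirror(self):
        # hand-built isosceles denticles: the mirror image is the same
        # polygon up to vertex reordering
        verts = np.array([
            [0, 0], [4, 0], [4, 1],
            [3.5, 1], [3.0, 2], [2.5, 1],
            [1.5, 1], [1.0, 2], [0.5, 1],
            [0, 1],
        ], float) * 1e-4
        prof = DenticleProfile(vertices=verts, model_length_L=4e-4,
                               orientation="rostral", denticle_height=1e-4,
                               baseline_thickness=1e-4, n_denticles=2,
                               apex_x=np.array([1.0e-4, 3.0e-4]))
        m = mirror_profile(prof)
        assert m.polygon().symmetric_difference(prof.polygon()).area \
            < 1e-12 * prof.area + 1e-30

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n=st.integers(2, 12), overhang=st.floats(0.0, 0.6),
           height=st.floats(2e-5, 1.2e-4))
    def test_mirror_properties_random_params(self, n, overhang, height):
        prof = make_idealized_profile(DenticleParams(
            n_denticles=n, tip_overhang=overhang, denticle_height=height))
        m = mirror_profile(prof)
        assert m.area == pytest.approx(prof.area, rel=1e-9)
        assert m.model_length_L == pytest.approx(prof.model_length_L,
                                                 rel=1e-9)
        back = mirror_profile(m)
        np.testing.assert_allclose(back.vertices, prof.vertices, atol=1e-12)


class TestDomain:
    def test_default_margins_follow_sizing_rule(self, idealized_profile):
        d = build_domain(idealized_profile)
        L = idealized_profile.model_length_L
        assert d.upstream_margin == pytest.approx(3 * L)
        assert d.downstream_margin == pytest.approx(20 * L)
        assert d.total_length == pytest.approx(24 * L)
        # published domain: 0.0575 m long, ~0.01 m high, = 23 L with L=2.5mm
        assert d.total_length >= 0.0575 * (L / 2.5e-3)
        assert d.baseline_midline_height_V1 == pytest.approx(d.height / 20)

    def test_margin_arithmetic_for_empirical_length(self):
        prof = make_empirical_profile(DenticleParams(perturbation_cv=0.25,
                                                     seed=1))
        d = build_domain(prof)
        assert d.upstream_margin >= 3 * 2.35e-3 * 0.95
        assert d.downstream_margin >= 20 * 2.35e-3 * 0.95

    def test_too_short_domain_rejected(self, idealized_profile):
        with pytest.raises(DomainError):
            build_domain(idealized_profile, height=1e-5)


def _square_bump_profile(s=1e-4):
    verts = np.array([[0, 0], [s, 0], [s, s], [0, s]], float)
    return DenticleProfile(vertices=verts, model_length_L=s,
                           orientation="rostral", denticle_height=s,
                           baseline_thickness=0.0, n_denticles=1,
                           apex_x=np.array([s / 2]))


class TestRasterize:
    def test_square_bump_exact(self):
        s = 1e-4
        prof = _square_bump_profile(s)
        dom = build_domain(prof, height=4e-4, upstream_factor=3,
                           downstream_factor=3)
        grid = rasterize(prof, dom, s / 10)
        # a 10x10 solid block
        assert int(grid.solid.sum()) == 100
        assert grid.solid_area() == pytest.approx(s * s)

    def test_area_converges_to_shoelace(self, idealized_profile):
        dom = build_domain(idealized_profile, height=6e-4,
                           upstream_factor=3, downstream_factor=3)
        grid = rasterize(idealized_profile, dom, 1e-5)
        exact = idealized_profile.area       # shapely shoelace area
        assert abs(grid.solid_area() - exact) / exact < 0.02

    def test_area_error_bounded_by_h_times_perimeter(self, small_profile):
        dom = build_domain(small_profile, height=6e-4, upstream_factor=3,
                           downstream_factor=3)
        exact = small_profile.area
        perim = small_profile.polygon().length
        for h in (1.2e-5, 6e-6):
            grid = rasterize(small_profile, dom, h)
            assert abs(grid.solid_area() - exact) <= h * perim

    def test_too_coarse_spacing_rejected(self, small_profile):
        dom = build_domain(small_profile, height=6e-4, upstream_factor=3,
                           downstream_factor=3)
        with pytest.raises(ResolutionError):
            rasterize(small_profile, dom, 4e-5)

    def test_graded_grid_matches_area_and_covers_domain(self, small_profile):
        dom = build_domain(small_profile, downstream_factor=10)
        grid = rasterize_graded(small_profile, dom, 1e-5)
        assert grid.xf[-1] == pytest.approx(dom.total_length, rel=1e-9)
        assert grid.yf[-1] == pytest.approx(dom.height, rel=1e-9)
        exact = small_profile.area
        assert abs(grid.solid_area() - exact) / exact < 0.03
        assert grid.dx.min() == pytest.approx(1e-5, rel=0.3)
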
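"""Vorticity, streamlines, recirculation detection, trimming, ooms."""

import math

import numpy as np
import pytest

from denticleflow.geometry import MaskGrid
from denticleflow.solver import FlowSolution, FluidProps
from denticleflow.postprocess import (vorticity, streamlines,
                                      detect_recirculation, trim_edges,
                                      order_of_magnitude, near_denticle_band)


def _solution_from_fields(u, v, h=1e-3, solid=None, U=1.0):
    nx, ny = u.shape
    if solid is None:
        solid = np.zeros((nx, ny), bool)
    dx = np.full(nx, h)
    dy = np.full(ny, h)
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    uf = np.zeros((nx + 1, ny))
    uf[1:-1] = 0.5 * (u[:-1] + u[1:])
    vf = np.zeros((nx, ny + 1))
    vf[:, 1:-1] = 0.5 * (v[:, :-1] + v[:, 1:])
    return FlowSolution(xc=xc, yc=yc, dx=dx, dy=dy, solid=solid, u=u, v=v,
                        p=np.zeros((nx, ny)), u_face=uf, v_face=vf,
                        drag_force_Fd=0.0, converged=True, U=U,
                        fluid=FluidProps())


class TestVorticity:
    def test_pure_shear(self):
        # u = k*y, v = 0 -> omega = -k
        h, k = 1e-3, 3.0
        yc = (np.arange(20) + 0.5) * h
        u = np.tile(k * yc, (30, 1))
        sol = _solution_from_fields(u, np.zeros_like(u), h)
        om = vorticity(sol)
        np.testing.assert_allclose(om, -k, rtol=1e-12)

    def test_solid_body_rotation(self):
        # u = -Omega*y, v = Omega*x -> omega = 2*Omega
        h, Om = 1e-3, 5.0
        xc = (np.arange(30) + 0.5) * h
        yc = (np.arange(20) + 0.5) * h
        u = np.tile(-Om * yc, (30, 1))
        v = np.tile((Om * xc)[:, None], (1, 20))
        sol = _solution_from_fields(u, v, h)
        np.testing.assert_allclose(vorticity(sol), 2 * Om, rtol=1e-12)

    def test_poiseuille_profile(self):
        # u(y) = 6U y (H - y)/H^2 -> omega = -6U(H - 2y)/H^2, 0 at midline
        h, U, ny = 1e-4, 0.2, 40
        H = ny * h
        yc = (np.arange(ny) + 0.5) * h
        u = np.tile(6 * U * yc * (H - yc) / H ** 2, (30, 1))
        sol = _solution_from_fields(u, np.zeros_like(u), h)
        om = vorticity(sol)
        exact = -6 * U * (H - 2 * yc) / H ** 2
        scale = np.abs(exact).max()
        assert np.abs(om[5:-5, 1:-1] - exact[1:-1]).max() / scale < 0.02
        mid = np.argmin(np.abs(yc - H / 2))
        assert abs(om[10, mid]) / scale < 0.03


class TestStreamlines:
    def test_uniform_flow_straight(self):
        u = np.full((50, 20), 1.0)
        sol = _solution_from_fields(u, np.zeros_like(u))
        (line,) = streamlines(sol, [(1e-3, 1.03e-2)])
        assert np.abs(line[:, 1] - 1.03e-2).max() < 1e-9
        assert line[-1, 0] > 0.045

    def test_seed_in_solid_skipped(self):
        u = np.full((50, 20), 1.0)
        solid = np.zeros((50, 20), bool)
        solid[10:20, :5] = True
        sol = _solution_from_fields(u, np.zeros_like(u), solid=solid)
        lines = streamlines(sol, [(15.5e-3, 2.5e-3)])
        assert lines == []

    def test_rankine_vortex_closes(self):
        # solid-body core inside a box: streamline in the core is a loop
        n, h = 60, 1e-3
        xc = (np.arange(n) + 0.5) * h
        yc = (np.arange(n) + 0.5) * h
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        x0 = y0 = n * h / 2
        Om = 10.0
        u = -Om * (Y - y0)
        v = Om * (X - x0)
        sol = _solution_from_fields(u, v, h)
        r0 = 8e-3
        (line,) = streamlines(sol, [(x0 + r0, y0)],
                              max_length=2.2 * math.pi * r0)
        r = np.hypot(line[:, 0] - x0, line[:, 1] - y0)
        assert np.abs(r - r0).max() / r0 < 0.01
        # passes back near the seed after one full revolution
        tail = line[len(line) // 2:]
        d_close = np.hypot(tail[:, 0] - (x0 + r0), tail[:, 1] - y0).min()
        assert d_close < 0.1 * r0

    def test_never_enters_solid(self):
        u = np.full((50, 20), 1.0)
        solid = np.zeros((50, 20), bool)
        solid[25:, :10] = True
        sol = _solution_from_fields(u, np.zeros_like(u), solid=solid)
        for line in streamlines(sol, [(1e-3, 5e-3)]):
            for x, y in line:
                i = min(int(x / 1e-3), 49)
                j = min(int(y / 1e-3), 19)
                assert not solid[i, j]


class TestTrimEdges:
    @pytest.mark.parametrize("n, nex, kept", [
        (20, 7, (8, 13)),
        (20, 5, (6, 15)),
        (10, 2, (3, 8)),
    ])
    def test_kept_range(self, n, nex, kept):
        assert trim_edges(n, nex) == kept

    def test_overtrim_rejected(self):
        with pytest.raises(ValueError):
            trim_edges(20, 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            trim_edges(40, 11)


class TestOrderOfMagnitude:
    @pytest.mark.parametrize("x, oom", [
        (2e-4, -4), (8e-4, -4), (100.0, 2), (1.0, 0), (9.99e-6, -6),
    ])
    def test_values(self, x, oom):
        assert order_of_magnitude(x) == oom

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            order_of_magnitude(0.0)


class TestRecirculationDetection:
    def _cavity_setup(self):
        """Two solid blocks on a floor with a vortex in the gap."""
        from denticleflow.geometry import (DenticleProfile, build_domain,
                                           rasterize)
        # two square 'denticles' built as an explicit profile
        verts = np.array([
            [0, 0], [5, 0], [5, 1],
            [4, 1], [4, 3], [3, 3], [3, 1],
            [2, 1], [2, 3], [1, 3], [1, 1],
            [0, 1],
        ], float) * 1e-4
        prof = DenticleProfile(vertices=verts, model_length_L=5e-4,
                               orientation="rostral", denticle_height=2e-4,
                               baseline_thickness=1e-4, n_denticles=2,
                               apex_x=np.array([1.5e-4, 3.5e-4]))
        dom = build_domain(prof, height=1.5e-3, upstream_factor=3,
                           downstream_factor=3)
        mask = rasterize(prof, dom, 2.5e-5)
        return prof, dom, mask

    def test_uniform_flow_no_zones(self):
        prof, dom, mask = self._cavity_setup()
        u = np.where(mask.solid, 0.0, 1.0)
        sol = _solution_from_fields(u, np.zeros_like(u), 2.5e-5,
                                    solid=mask.solid)
        sol.dx, sol.dy = mask.dx, mask.dy
        sol.xc, sol.yc = mask.xc, mask.yc
        zones = detect_recirculation(sol, mask, prof, dom, n_exclude=0)
        assert zones == []

    def test_constructed_vortex_in_gap(self):
        prof, dom, mask = self._cavity_setup()
        xc, yc = mask.xc, mask.yc
        u = np.where(mask.solid, 0.0, 1.0)
        v = np.zeros_like(u)
        # place a vortex centered in the inter-block gap
        x0 = dom.upstream_margin + 2.5e-4
        y0 = 2.0e-4
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        core = np.hypot(X - x0, Y - y0) < 1.0e-4
        u[core] = -(Y[core] - y0) * 2e4
        v[core] = (X[core] - x0) * 2e4
        u[mask.solid] = 0.0
        v[mask.solid] = 0.0
        sol = _solution_from_fields(u, v, 2.5e-5, solid=mask.solid)
        sol.dx, sol.dy = mask.dx, mask.dy
        sol.xc, sol.yc = mask.xc, mask.yc
        zones = detect_recirculation(sol, mask, prof, dom, eps=1e-3,
                                     n_exclude=0)
        assert len(zones) == 1
        assert zones[0].gap_index == 1
        assert zones[0].peak_reversed_speed > 0.5

    def test_near_denticle_band_geometry(self):
        prof, dom, mask = self._cavity_setup()
        band = near_denticle_band(mask, prof.denticle_height)
        yc = mask.yc
        assert band.any()
        assert not (band & mask.solid).any()
        # band never extends above one denticle height over the tallest solid
        jmax = np.nonzero(band.any(axis=0))[0].max()
        top_solid = yc[np.nonzero(mask.solid.any(axis=0))[0]].max()
        assert yc[jmax] <= top_solid + prof.denticle_height + 2.5e-5
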
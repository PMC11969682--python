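"""Solver validation against closed forms and internal oracles.

Each case returns the measured error(s) so tests can assert the
contracts: Poiseuille within 2% pointwise, Couette vorticity within 2%,
global mass conservation within 0.1%, Stokes-regime linearity within 1%,
and mirror equivalence of reversed-flow vs mirrored-geometry solutions.
"""

from __future__ import annotations

import numpy as np

from .geometry import MaskGrid, DenticleParams, make_idealized_profile
from .solver import FluidProps, SolverConfig, solve_steady, drag_force, \
    drag_force_cv
from .postprocess import vorticity


def _channel_mask(h: float, H: float, Lx: float) -> MaskGrid:
    nx, ny = int(round(Lx / h)), int(round(H / h))
    return MaskGrid(h, nx, ny, np.zeros((nx, ny), bool), (0.0, 0.0),
                    np.full(nx, h), np.full(ny, h))


def poiseuille_case(U: float = 0.01, H: float = 4e-4, Lx: float = 2e-3,
                    h: float = 2e-5, fluid: FluidProps | None = None):
    """Plane channel with no-slip top and floor and an imposed parabolic
    inlet profile; returns (max pointwise deviation / U_max, solution)."""
    fluid = fluid or FluidProps()
    mask = _channel_mask(h, H, Lx)
    yc = mask.yc
    prof = 6 * U * yc * (H - yc) / H ** 2
    cfg = SolverConfig(inlet_velocity_U=U, spacing_h=h, top_bc="noslip",
                       inlet_profile=prof, initialize="zero",
                       max_iterations=100_000)
    sol = solve_steady(mask, None, fluid, cfg)
    mid = sol.u[mask.nx // 2, :]
    err = float(np.abs(mid - prof).max() / prof.max())
    return err, sol


def poiseuille_wall_drag_case(U: float = 0.01, H: float = 4e-4,
                              Lx: float = 2e-3, h: float = 1e-5,
                              fluid: FluidProps | None = None):
    """Channel over a solid floor slab; compares the integrated slab drag
    with the analytic wall shear 6*mu*U/H * l, and the control-volume
    estimate with the analytic drag of both no-slip walls."""
    fluid = fluid or FluidProps()
    slab_rows = 3
    nx, ny = int(round(Lx / h)), int(round(H / h)) + slab_rows
    solid = np.zeros((nx, ny), bool)
    solid[:, :slab_rows] = True
    mask = MaskGrid(h, nx, ny, solid, (0.0, 0.0), np.full(nx, h),
                    np.full(ny, h))
    yc = mask.yc - slab_rows * h          # height above the slab
    prof = np.where(yc > 0, 6 * U * yc * (H - yc) / H ** 2, 0.0)
    cfg = SolverConfig(inlet_velocity_U=U, spacing_h=h, top_bc="noslip",
                       inlet_profile=prof, initialize="zero",
                       max_iterations=100_000)
    sol = solve_steady(mask, None, fluid, cfg)
    fd = drag_force(sol, mask, fluid)
    analytic = 6 * fluid.dynamic_viscosity_mu * U / H * Lx
    err = abs(fd - analytic) / analytic
    # the control volume encloses both no-slip walls (slab + top)
    cv = drag_force_cv(sol, mask, fluid)
    err_cv = abs(cv - 2 * analytic) / (2 * analytic)
    return float(err), float(err_cv), float(fd), float(analytic)


def couette_case(U: float = 0.01, H: float = 4e-4, Lx: float = 2e-3,
                 h: float = 2e-5, fluid: FluidProps | None = None):
    """Plane Couette flow driven by a moving top wall; the vorticity of the
    exact solution u = U*y/H is -U/H everywhere.  Returns the max relative
    vorticity deviation over the interior."""
    fluid = fluid or FluidProps()
    mask = _channel_mask(h, H, Lx)
    yc = mask.yc
    prof = U * yc / H
    cfg = SolverConfig(inlet_velocity_U=U, spacing_h=h, top_bc="moving",
                       top_u=U, inlet_profile=prof, initialize="zero",
                       max_iterations=100_000)
    sol = solve_steady(mask, None, fluid, cfg)
    om = vorticity(sol)
    interior = om[mask.nx // 4: 3 * mask.nx // 4, 1:-1]
    target = -U / H
    err = float(np.abs(interior - target).max() / abs(target))
    return err, sol


def mass_conservation_error(sol) -> float:
    """Relative inlet/outlet volumetric flux imbalance."""
    qin, qout = sol.inlet_flux(), sol.outlet_flux()
    return abs(qin - qout) / abs(qin)


def _small_denticle_setup(h: float = 1e-5, n: int = 3, H: float = 6e-4):
    """Few-denticle mask on a short symmetric-margin uniform grid, used by
    the mirror and Stokes checks."""
    from dataclasses import replace
    from .geometry import build_domain, rasterize
    prof = make_idealized_profile(DenticleParams(n_denticles=n))
    dom = build_domain(prof, height=H, upstream_factor=3.0,
                       downstream_factor=3.0)
    mask = rasterize(prof, dom, h)
    # the caudal mask is the exact x-flip of the rostral one (the
    # rasterization of the mirrored polygon on the reflected grid), so the
    # comparison isolates the solver's reversed-flow symmetry
    mask_m = replace(mask, solid=mask.solid[::-1].copy())
    return mask, mask_m


def mirror_equivalence_error(U: float = 0.05, h: float = 1e-5,
                             fluid: FluidProps | None = None) -> float:
    """Solves the caudal (mirrored) geometry with normal left-to-right flow
    and the rostral geometry with the flow reversed (inlet and outlet
    swapped); the x-reflection of the latter must reproduce the former.
    Returns max field difference / U."""
    fluid = fluid or FluidProps()
    mask, mask_m = _small_denticle_setup(h=h)
    cfg_f = SolverConfig(inlet_velocity_U=U, spacing_h=h,
                         max_iterations=150_000, drag_stall_tol=1e-4)
    sol_caudal = solve_steady(mask_m, None, fluid, cfg_f)
    cfg_r = SolverConfig(inlet_velocity_U=U, spacing_h=h,
                         max_iterations=150_000, drag_stall_tol=1e-4,
                         flow_direction=-1)
    sol_rev = solve_steady(mask, None, fluid, cfg_r)
    du = np.abs(sol_caudal.u - (-sol_rev.u[::-1, :])).max()
    dv = np.abs(sol_caudal.v - sol_rev.v[::-1, :]).max()
    return float(max(du, dv) / U)


def stokes_linearity_error(U1: float = 1e-4, h: float = 1e-5,
                           fluid: FluidProps | None = None) -> float:
    """At Re << 1 the steady flow is linear in the driving speed: doubling
    the inlet velocity must double the velocity field.  Returns the max
    deviation of (sol2 - 2*sol1) relative to 2*U1."""
    fluid = fluid or FluidProps()
    mask, _ = _small_denticle_setup(h=h, n=2, H=4e-4)
    sols = []
    for U in (U1, 2 * U1):
        cfg = SolverConfig(inlet_velocity_U=U, spacing_h=h,
                           max_iterations=120_000, drag_stall_tol=1e-4)
        sols.append(solve_steady(mask, None, fluid, cfg))
    du = np.abs(sols[1].u - 2 * sols[0].u).max()
    dv = np.abs(sols[1].v - 2 * sols[0].v).max()
    return float(max(du, dv) / (2 * U1))


def cavity_case(Re: float = 100.0, n: int = 48,
                fluid: FluidProps | None = None):
    """Lid-driven square cavity built from solid side walls and a moving
    top; returns the primary-vortex center (x, y) in lid units along with
    the solution, for self-convergence checks against a finer grid."""
    fluid = fluid or FluidProps()
    nu = fluid.kinematic_viscosity_nu
    Lbox = 1e-3
    U = Re * nu / Lbox
    h = Lbox / n
    nx = n + 2                       # one solid column each side
    ny = n
    solid = np.zeros((nx, ny), bool)
    solid[0, :] = True
    solid[-1, :] = True
    mask = MaskGrid(h, nx, ny, solid, (0.0, 0.0), np.full(nx, h),
                    np.full(ny, h))
    cfg = SolverConfig(inlet_velocity_U=U, spacing_h=h, top_bc="moving",
                       top_u=U, inlet_profile=np.zeros(ny),
                       initialize="zero", max_iterations=200_000,
                       convergence_tol=1e-7)
    sol = solve_steady(mask, None, fluid, cfg)
    # streamfunction from u: psi(y) = int u dy per column
    psi = np.cumsum(sol.u * sol.dy[None, :], axis=1)
    psi[solid] = 0.0
    i, j = np.unravel_index(np.argmin(psi), psi.shape)
    x_rel = (sol.xc[i] - h) / Lbox
    y_rel = sol.yc[j] / Lbox
    return (float(x_rel), float(y_rel)), sol
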
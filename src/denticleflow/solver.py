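"""Steady 2D incompressible laminar flow around a solid mask.

The flow model matches the published virtual-flume setup: uniform normal
inflow on one side, zero-gauge-pressure outlet on the other, slip-symmetry
("open") top, no-slip floor and model surface.  The steady state is reached
by artificial-compressibility pseudo-time iteration with local time steps;
convergence is declared on residuals or on a stalled drag force, and
non-convergence is reported, never raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import MaskGrid, FlowDomain

log = logging.getLogger(__name__)

LAMINAR_RE_LIMIT = 2000.0

# Reynolds numbers are conventionally reported with nu = 1.0e-6 m^2/s for
# water; the simulated fluid uses the tabulated density and viscosity below.
NU_REPORT = 1.0e-6


class SolverInstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProps:
    """Water at ~20 C (standard CFD property-table values)."""

    density_rho: float = 998.2
    dynamic_viscosity_mu: float = 1.003e-3

    @property
    def kinematic_viscosity_nu(self) -> float:
        return self.dynamic_viscosity_mu / self.density_rho

    def __post_init__(self):
        if self.density_rho <= 0 or self.dynamic_viscosity_mu <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass
class SolverConfig:
    inlet_velocity_U: float = 0.05
    spacing_h: float = 1.0e-5
    convergence_tol: float = 1.0e-6
    max_iterations: int = 120_000
    drag_stall_tol: float = 1.0e-3      # relative drag change ...
    drag_stall_window: int = 1000       # ... over this many iterations
    check_every: int = 500
    cfl: float = 0.6
    ac_speed_factor: float = 2.5        # artificial sound speed c = factor * U
    speed_max_factor: float = 1.6       # stability bound on |u| as multiple of U
    top_bc: str = "slip"                # slip | noslip | moving
    top_u: float = 0.0
    inlet_profile: np.ndarray | None = None   # per-row u at the inlet
    flow_direction: int = +1            # +1: inlet west; -1: inlet east
    initialize: str = "boundary_layer"  # or "uniform", "zero"

    def __post_init__(self):
        if self.inlet_velocity_U <= 0:
            raise ValueError("inlet velocity must be positive")
        if not (0 < self.convergence_tol < 1 and 0 < self.drag_stall_tol < 1):
            raise ValueError("tolerances must lie in (0, 1)")


@dataclass
class FlowSolution:
    """Converged (or diagnostic) steady fields on the solver grid.

    ``u``, ``v`` and ``p`` are cell-centered; the staggered face fields are
    kept for exact flux/divergence computations.  Pressure is gauge (Pa),
    zero at the outlet.
    """

    xc: np.ndarray
    yc: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    solid: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    u_face: np.ndarray
    v_face: np.ndarray
    drag_force_Fd: float
    residual_history: list = field(default_factory=list)
    converged: bool = False
    mode: str = "none"              # residual | drag_stall | none
    iterations: int = 0
    U: float = 0.0
    fluid: FluidProps = field(default_factory=FluidProps)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def inlet_flux(self) -> float:
        return float((self.u_face[0] * self.dy).sum())

    def outlet_flux(self) -> float:
        return float((self.u_face[-1] * self.dy).sum())


def reynolds(U: float, L: float, nu: float = NU_REPORT) -> float:
    """Re = U*L/nu.  With the reporting viscosity 1e-6 m^2/s this
    reproduces the published values (e.g. 0.05 m/s x 0.0025 m -> 125)."""
    if U <= 0 or L <= 0 or nu <= 0:
        raise ValueError("Reynolds number inputs must be positive")
    return U * L / nu


def _face_blocks(solid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = solid.shape
    ublock = np.zeros((nx + 1, ny), dtype=np.bool_)
    ublock[1:nx] = solid[:-1] | solid[1:]
    ublock[0] = solid[0]
    ublock[nx] = solid[-1]
    vblock = np.zeros((nx, ny + 1), dtype=np.bool_)
    vblock[:, 1:ny] = solid[:, :-1] | solid[:, 1:]
    vblock[:, 0] = solid[:, 0]
    vblock[:, ny] = solid[:, -1]
    return ublock, vblock


def _local_dt(dxa: np.ndarray, dya: np.ndarray, s: float, c: float,
              nu: float, cfl: float) -> np.ndarray:
    """Stable pseudo-time step per node from advective+acoustic and viscous
    limits; dxa/dya broadcast to the node shape."""
    adv = (s + c) / dxa + (s + c) / dya
    visc = 2.0 * nu * (1.0 / dxa ** 2 + 1.0 / dya ** 2)
    return cfl / (adv + visc)


def solve_steady(mask: MaskGrid, domain: FlowDomain | None,
                 fluid: FluidProps, config: SolverConfig) -> FlowSolution:
    """March the artificial-compressibility system to a steady state.

    Returns a FlowSolution; ``converged`` is False (with diagnostics in
    ``residual_history``) if neither the residual criterion nor the
    drag-stall criterion is met within ``max_iterations``.
    """
    U = config.inlet_velocity_U
    nu = fluid.kinematic_viscosity_nu
    nx, ny = mask.nx, mask.ny
    solid = np.ascontiguousarray(mask.solid)
    xc, yc = mask.xc, mask.yc
    xf, yf = mask.xf, mask.yf
    dx, dy = mask.dx, mask.dy

    if domain is not None:
        Lmodel = _model_length(mask)
        Re = reynolds(U, Lmodel, NU_REPORT) if Lmodel > 0 else 0.0
        if Re >= LAMINAR_RE_LIMIT:
            raise ValueError(
                f"Re = {Re:.0f} exceeds the laminar limit {LAMINAR_RE_LIMIT}")

    ublock, vblock = _face_blocks(solid)

    # inlet profile (plug flow by default)
    if config.inlet_profile is not None:
        inlet = np.asarray(config.inlet_profile, float)
        if inlet.shape != (ny,):
            raise ValueError("inlet_profile must have one value per row")
    else:
        inlet = np.full(ny, U)
    inlet_side = 0 if config.flow_direction >= 0 else 1
    sgn = 1.0 if inlet_side == 0 else -1.0
    inlet = sgn * np.abs(inlet)
    p_col = nx - 1 if inlet_side == 0 else 0

    # initial guess
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    if config.initialize == "uniform":
        u[:] = sgn * U
    elif config.initialize == "boundary_layer":
        x_mid = 0.5 * (xc[0] + xc[-1])
        delta = max(5.0 * math.sqrt(nu * max(x_mid, dx[0]) / U), 4 * dy[0])
        prof = np.minimum(1.0, yc / delta)
        u[:] = sgn * U * prof[None, :]
    _kernels.enforce_bcs(u, v, ublock, vblock, inlet, inlet_side)

    smax = config.speed_max_factor * U
    c = config.ac_speed_factor * U + 10.0 * nu / float(dx.sum())
    c2 = c * c
    cfl = config.cfl

    dxu = np.r_[dx[0], np.minimum(dx[:-1], dx[1:]), dx[-1]][:, None] * np.ones(ny)[None, :]
    dyu = dy[None, :] * np.ones(nx + 1)[:, None]
    dtu = _local_dt(dxu, dyu, smax, c, nu, cfl)
    dxv = dx[:, None] * np.ones(ny + 1)[None, :]
    dyv = np.r_[dy[0], np.minimum(dy[:-1], dy[1:]), dy[-1]][None, :] * np.ones(nx)[:, None]
    dtv = _local_dt(dxv, dyv, smax, c, nu, cfl)
    dtp = _local_dt(dx[:, None] * np.ones(ny)[None, :],
                    dy[None, :] * np.ones(nx)[:, None], smax, c, 0.0, cfl)

    un, vn, pn = u.copy(), v.copy(), p.copy()
    history: list[tuple[int, float, float, float]] = []
    converged = False
    mode = "none"
    it = 0
    block = config.check_every - (config.check_every % 2)  # keep buffers aligned
    block = max(block, 2)
    drag_trail: list[tuple[int, float]] = []

    while it < config.max_iterations:
        res_u, res_div = _kernels.run_block(
            u, v, p, un, vn, pn, solid, ublock, vblock,
            xc, yc, xf, yf, dx, dy, dtu, dtv, dtp,
            nu, c2, inlet, inlet_side, _top_code(config.top_bc),
            config.top_u, p_col, block)
        it += block
        if not np.isfinite(u).all() or not np.isfinite(p).all():
            raise SolverInstabilityError(
                f"solution diverged at iteration {it} "
                f"(U={U}, h={config.spacing_h}, c={c:.3g}); "
                "reduce cfl or refine the grid")
        sol_tmp = _assemble(mask, fluid, u, v, p, U)
        fd = drag_force(sol_tmp, mask, fluid, warn_unconverged=False)
        res_mom = res_u / U
        res_c = res_div / (U * mask.spacing_h)
        history.append((it, res_mom, res_c, fd))
        drag_trail.append((it, fd))
        while drag_trail and drag_trail[0][0] < it - config.drag_stall_window:
            drag_trail.pop(0)
        if res_mom < config.convergence_tol and res_c < config.convergence_tol:
            converged, mode = True, "residual"
            break
        if (solid.any() and len(drag_trail) >= 2
                and drag_trail[-1][0] - drag_trail[0][0] >= config.drag_stall_window - block
                and it >= 2 * config.drag_stall_window
                and res_mom < 100 * config.convergence_tol):
            fds = [f for _, f in drag_trail]
            ref = max(abs(fds[-1]), 1e-300)
            if (max(fds) - min(fds)) / ref < config.drag_stall_tol:
                converged, mode = True, "drag_stall"
                break

    sol = _assemble(mask, fluid, u, v, p, U)
    sol.residual_history = history
    sol.converged = converged
    sol.mode = mode
    sol.iterations = it
    sol.drag_force_Fd = drag_force(sol, mask, fluid,
                                   warn_unconverged=not converged)
    if not converged:
        log.warning("solver did not converge in %d iterations "
                    "(res_mom=%.2e, res_cont=%.2e)", it,
                    history[-1][1] if history else float("nan"),
                    history[-1][2] if history else float("nan"))
    else:
        log.info("converged (%s) after %d iterations, drag %.4g N/m",
                 mode, it, sol.drag_force_Fd)
    return sol


def _top_code(name: str) -> int:
    return {"slip": _kernels.TOP_SLIP, "noslip": _kernels.TOP_NOSLIP,
            "moving": _kernels.TOP_MOVING}[name]


def _model_length(mask: MaskGrid) -> float:
    cols = mask.solid.any(axis=1)
    if not cols.any():
        return 0.0
    idx = np.flatnonzero(cols)
    xf = mask.xf
    return float(xf[idx[-1] + 1] - xf[idx[0]])


def _assemble(mask: MaskGrid, fluid: FluidProps, u, v, p, U) -> FlowSolution:
    uc = 0.5 * (u[:-1, :] + u[1:, :])
    vc = 0.5 * (v[:, :-1] + v[:, 1:])
    uc[mask.solid] = 0.0
    vc[mask.solid] = 0.0
    return FlowSolution(
        xc=mask.xc, yc=mask.yc, dx=mask.dx, dy=mask.dy, solid=mask.solid,
        u=uc, v=vc, p=p * fluid.density_rho, u_face=u, v_face=v,
        drag_force_Fd=0.0, U=U, fluid=fluid)


def drag_force(solution: FlowSolution, mask: MaskGrid, fluid: FluidProps,
               warn_unconverged: bool = True) -> float:
    """Streamwise force per unit depth on the solid model.

    Pressure acts on vertical solid faces; viscous shear on horizontal
    faces uses a two-point (quadratic, zero at the wall) one-sided fit,
    exact for a parabolic near-wall profile.
    """
    if warn_unconverged and not solution.converged:
        log.warning("drag evaluated on an unconverged solution")
    solid = mask.solid
    nx, ny = solid.shape
    p = solution.p
    u = solution.u
    dx, dy = mask.dx, mask.dy
    yc = mask.yc
    mu = fluid.dynamic_viscosity_mu
    fx = 0.0

    fluid_w = np.zeros_like(solid)
    fluid_w[1:, :] = solid[1:, :] & ~solid[:-1, :]   # solid with fluid west
    fluid_e = np.zeros_like(solid)
    fluid_e[:-1, :] = solid[:-1, :] & ~solid[1:, :]  # solid with fluid east
    for i, j in zip(*np.nonzero(fluid_w)):
        fx += p[i - 1, j] * dy[j]
    for i, j in zip(*np.nonzero(fluid_e)):
        fx -= p[i + 1, j] * dy[j]

    def shear(u1, d1, u2, d2):
        # du/dy at the wall from u(0)=0, u(d1)=u1, u(d2)=u2
        if d2 is None:
            return u1 / d1
        return (u1 * d2 * d2 - u2 * d1 * d1) / (d1 * d2 * (d2 - d1))

    top_solid = solid[:, :-1] & ~solid[:, 1:]        # fluid above solid
    for i, j in zip(*np.nonzero(top_solid)):
        jw = j + 1                                   # first fluid cell
        ywall = mask.yf[jw]
        d1 = yc[jw] - ywall
        if jw + 1 < ny and not solid[i, jw + 1]:
            fx += mu * shear(u[i, jw], d1, u[i, jw + 1], yc[jw + 1] - ywall) * dx[i]
        else:
            fx += mu * shear(u[i, jw], d1, None, None) * dx[i]
    bot_solid = ~solid[:, :-1] & solid[:, 1:]        # fluid below solid
    for i, j in zip(*np.nonzero(bot_solid)):
        jw = j                                       # first fluid cell below
        ywall = mask.yf[jw + 1]
        d1 = ywall - yc[jw]
        if jw - 1 >= 0 and not solid[i, jw - 1]:
            fx += mu * shear(u[i, jw], d1, u[i, jw - 1], ywall - yc[jw - 1]) * dx[i]
        else:
            fx += mu * shear(u[i, jw], d1, None, None) * dx[i]
    return float(fx)


def drag_force_cv(solution: FlowSolution, mask: MaskGrid,
                  fluid: FluidProps) -> float:
    """Control-volume momentum-flux estimate of the model drag.

    Integrates momentum and pressure over the inlet/outlet columns and
    subtracts floor shear outside the model footprint; serves as an
    independent cross-check of the surface-traction sum.
    """
    rho = fluid.density_rho
    mu = fluid.dynamic_viscosity_mu
    dy, dx = mask.dy, mask.dx
    u = solution.u
    p = solution.p
    uin, pin = u[0, :], p[0, :]
    uout, pout = u[-1, :], p[-1, :]
    fx = float(((rho * uin ** 2 + pin) * dy).sum()
               - ((rho * uout ** 2 + pout) * dy).sum())
    cols = mask.solid.any(axis=1)
    floor_free = ~cols
    d1 = mask.yc[0]
    tau = mu * u[:, 0] / d1
    fx -= float((tau * dx)[floor_free].sum())
    return fx
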
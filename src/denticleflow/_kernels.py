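"""Numba kernels for the artificial-compressibility steady flow iteration.

Staggered (MAC) layout on a rectilinear grid:
  u[i, j] at (xf[i], yc[j]), shape (nx+1, ny)   -- x-velocity on vertical faces
  v[i, j] at (xc[i], yf[j]), shape (nx, ny+1)   -- y-velocity on horizontal faces
  p[i, j] at (xc[i], yc[j]), shape (nx, ny)     -- kinematic pressure p/rho
Solid cells carry zero velocity on all their faces (stair-step no-slip);
tangential no-slip at walls enters through antisymmetric ghost values at
half-cell distance.  Advection is first-order upwind; each unknown marches
with its own pseudo-time step (steady state only is meaningful).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TOP_SLIP = 0
TOP_NOSLIP = 1
TOP_MOVING = 2


@njit(cache=True)
def enforce_bcs(u, v, ublock, vblock, inlet_profile, inlet_side):
    nx1, ny = u.shape
    nx = nx1 - 1
    # blocked (solid-adjacent) faces
    for i in range(nx + 1):
        for j in range(ny):
            if ublock[i, j]:
                u[i, j] = 0.0
    for i in range(nx):
        for j in range(ny + 1):
            if vblock[i, j]:
                v[i, j] = 0.0
        v[i, 0] = 0.0
        v[i, ny] = 0.0
    if inlet_side == 0:
        for j in range(ny):
            if not ublock[0, j]:
                u[0, j] = inlet_profile[j]
            u[nx, j] = u[nx - 1, j]
        for j in range(ny + 1):
            if not vblock[nx - 1, j]:
                v[nx - 1, j] = v[nx - 2, j]
    else:
        for j in range(ny):
            if not ublock[nx, j]:
                u[nx, j] = inlet_profile[j]
            u[0, j] = u[1, j]
        for j in range(ny + 1):
            if not vblock[0, j]:
                v[0, j] = v[1, j]


@njit(cache=True)
def step(u, v, p, un, vn, pn, solid, ublock, vblock,
         xc, yc, xf, yf, dx, dy, dtu, dtv, dtp,
         nu, c2, inlet_profile, inlet_side, top_bc, top_u, p_col):
    """One pseudo-time step; writes updated fields into un, vn, pn."""
    nx, ny = p.shape

    # --- u momentum ---------------------------------------------------
    for i in range(1, nx):
        for j in range(ny):
            if ublock[i, j]:
                un[i, j] = 0.0
                continue
            uc = u[i, j]
            # x-advection (upwind between u-faces)
            if uc > 0.0:
                dudx = (uc - u[i - 1, j]) / (xf[i] - xf[i - 1])
            else:
                dudx = (u[i + 1, j] - uc) / (xf[i + 1] - xf[i])
            # transverse velocity at the u-face
            vm = 0.25 * (v[i - 1, j] + v[i, j] + v[i - 1, j + 1] + v[i, j + 1])
            # neighbours in y with wall ghosts
            wall_s = (j == 0) or ublock[i, j - 1]
            if wall_s:
                us = -uc
                ds = dy[j]
            else:
                us = u[i, j - 1]
                ds = yc[j] - yc[j - 1]
            if j == ny - 1:
                if top_bc == TOP_SLIP:
                    unb = uc
                elif top_bc == TOP_NOSLIP:
                    unb = -uc
                else:
                    unb = 2.0 * top_u - uc
                dn = dy[j]
            elif ublock[i, j + 1]:
                unb = -uc
                dn = dy[j]
            else:
                unb = u[i, j + 1]
                dn = yc[j + 1] - yc[j]
            if vm > 0.0:
                dudy = (uc - us) / ds
            else:
                dudy = (unb - uc) / dn
            d2udx2 = ((u[i + 1, j] - uc) / (xf[i + 1] - xf[i])
                      - (uc - u[i - 1, j]) / (xf[i] - xf[i - 1])) \
                / (0.5 * (xf[i + 1] - xf[i - 1]))
            d2udy2 = ((unb - uc) / dn - (uc - us) / ds) / dy[j]
            gradp = (p[i, j] - p[i - 1, j]) / (xc[i] - xc[i - 1])
            un[i, j] = uc + dtu[i, j] * (-uc * dudx - vm * dudy
                                         + nu * (d2udx2 + d2udy2) - gradp)

    # --- v momentum ---------------------------------------------------
    for i in range(nx):
        for j in range(1, ny):
            if vblock[i, j]:
                vn[i, j] = 0.0
                continue
            vc = v[i, j]
            um = 0.25 * (u[i, j - 1] + u[i + 1, j - 1] + u[i, j] + u[i + 1, j])
            wall_w = (i == 0 and inlet_side == 0) or (i > 0 and vblock[i - 1, j])
            if wall_w:
                vw = -vc
                dw = dx[i]
            elif i == 0:
                vw = vc
                dw = dx[i]
            else:
                vw = v[i - 1, j]
                dw = xc[i] - xc[i - 1]
            wall_e = (i == nx - 1 and inlet_side == 1) or \
                     (i < nx - 1 and vblock[i + 1, j])
            if wall_e:
                ve = -vc
                de = dx[i]
            elif i == nx - 1:
                ve = vc
                de = dx[i]
            else:
                ve = v[i + 1, j]
                de = xc[i + 1] - xc[i]
            if um > 0.0:
                dvdx = (vc - vw) / dw
            else:
                dvdx = (ve - vc) / de
            if vc > 0.0:
                dvdy = (vc - v[i, j - 1]) / (yf[j] - yf[j - 1])
            else:
                dvdy = (v[i, j + 1] - vc) / (yf[j + 1] - yf[j])
            d2vdx2 = ((ve - vc) / de - (vc - vw) / dw) / dx[i]
            d2vdy2 = ((v[i, j + 1] - vc) / (yf[j + 1] - yf[j])
                      - (vc - v[i, j - 1]) / (yf[j] - yf[j - 1])) \
                / (0.5 * (yf[j + 1] - yf[j - 1]))
            gradp = (p[i, j] - p[i, j - 1]) / (yc[j] - yc[j - 1])
            vn[i, j] = vc + dtv[i, j] * (-um * dvdx - vc * dvdy
                                         + nu * (d2vdx2 + d2vdy2) - gradp)
    for i in range(nx):
        vn[i, 0] = 0.0
        vn[i, ny] = 0.0

    # --- pressure (artificial compressibility) -------------------------
    for i in range(nx):
        for j in range(ny):
            if solid[i, j] or i == p_col:
                pn[i, j] = 0.0
            else:
                div = (un[i + 1, j] - un[i, j]) / dx[i] \
                    + (vn[i, j + 1] - vn[i, j]) / dy[j]
                pn[i, j] = p[i, j] - dtp[i, j] * c2 * div

    enforce_bcs(un, vn, ublock, vblock, inlet_profile, inlet_side)


@njit(cache=True)
def run_block(u, v, p, un, vn, pn, solid, ublock, vblock,
              xc, yc, xf, yf, dx, dy, dtu, dtv, dtp,
              nu, c2, inlet_profile, inlet_side, top_bc, top_u, p_col,
              nsteps):
    """Advance ``nsteps`` pseudo-time steps; returns (max|du|, max|div*h/1|).

    Field arrays are updated in place (ping-pong between the two buffers,
    ending with the result in the first set).
    """
    res_u = 0.0
    for k in range(nsteps):
        step(u, v, p, un, vn, pn, solid, ublock, vblock,
             xc, yc, xf, yf, dx, dy, dtu, dtv, dtp,
             nu, c2, inlet_profile, inlet_side, top_bc, top_u, p_col)
        u, un = un, u
        v, vn = vn, v
        p, pn = pn, p
    # final buffers: if nsteps odd the roles swapped an odd number of times
    res_u = 0.0
    nx, ny = p.shape
    for i in range(nx + 1):
        for j in range(ny):
            d = abs(u[i, j] - un[i, j])
            if d > res_u:
                res_u = d
    res_div = 0.0
    for i in range(nx):
        if i == p_col:
            continue        # outlet column: p is Dirichlet, div unconstrained
        for j in range(ny):
            if not solid[i, j]:
                div = (u[i + 1, j] - u[i, j]) / dx[i] \
                    + (v[i, j + 1] - v[i, j]) / dy[j]
                d = abs(div) * min(dx[i], dy[j])
                if d > res_div:
                    res_div = d
    return res_u, res_div


@njit(cache=True)
def divergence_max(u, v, solid, dx, dy):
    nx, ny = solid.shape
    m = 0.0
    for i in range(nx):
        for j in range(ny):
            if not solid[i, j]:
                div = (u[i + 1, j] - u[i, j]) / dx[i] \
                    + (v[i, j + 1] - v[i, j]) / dy[j]
                d = abs(div) * min(dx[i], dy[j])
                if d > m:
                    m = d
    return m
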
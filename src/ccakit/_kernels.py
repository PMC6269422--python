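"""Numba kernels for Brownian walks with structured environments and
Gaussian-detection rendering.  All lengths are micrometers, times seconds.

Environment codes: 0 free, 1 microdomain, 2 meshwork, 3 barrier,
4 excluded sphere, 5 confined cells.  ``env_p`` packs the kind-specific
parameters (see ``simulate.EnvironmentSpec``).
"""

import numpy as np
from numba import njit

ENV_FREE = 0
ENV_MICRODOMAIN = 1
ENV_MESHWORK = 2
ENV_BARRIER = 3
ENV_EXCLUDED = 4
ENV_CONFINED = 5

# exp(-13) ~ 2e-6: detection weights below this are dropped.
_ARG_CUT = 13.0


@njit(cache=True, inline="always", fastmath=True)
def _step_particle(x, y, z, dx, dy, dz, u1, u2, bx, by, bz, env, p):
    """One environment-aware displacement; returns the new position."""
    nx = x + dx
    ny = y + dy
    nz = z + dz
    if env == ENV_MICRODOMAIN:
        pitch = p[0]
        R2 = p[1] * p[1]
        gx = np.rint(x / pitch) * pitch
        gy = np.rint(y / pitch) * pitch
        inside_old = (x - gx) ** 2 + (y - gy) ** 2 < R2
        if inside_old:
            if (nx - gx) ** 2 + (ny - gy) ** 2 >= R2 and u1 >= p[2]:
                # exit attempt rejected: keep the lateral position
                nx = x
                ny = y
    elif env == ENV_MESHWORK:
        pitch = p[0]
        if np.floor(nx / pitch) != np.floor(x / pitch) and u1 >= p[1]:
            edge = pitch * (np.floor(x / pitch) + (1.0 if dx > 0 else 0.0))
            nx = 2.0 * edge - nx
        if np.floor(ny / pitch) != np.floor(y / pitch) and u2 >= p[1]:
            edge = pitch * (np.floor(y / pitch) + (1.0 if dy > 0 else 0.0))
            ny = 2.0 * edge - ny
    elif env == ENV_BARRIER:
        x0 = p[0]
        h = p[1]
        lo = x0 - h
        hi = x0 + h
        if x < lo:
            if nx > lo and (nx > hi and u1 < p[2]):
                pass  # permeation accepted
            elif nx > lo:
                nx = 2.0 * lo - nx
        elif x > hi:
            if nx < hi and (nx < lo and u1 < p[2]):
                pass
            elif nx < hi:
                nx = 2.0 * hi - nx
        # reflecting box walls along x (the barrier axis is not periodic)
        if nx > 0.5 * bx:
            nx = bx - nx
        elif nx < -0.5 * bx:
            nx = -bx - nx
    elif env == ENV_EXCLUDED:
        ddx = nx - p[0]
        ddy = ny - p[1]
        ddz = nz - p[2]
        if ddx * ddx + ddy * ddy + ddz * ddz < p[3] * p[3]:
            nx = x
            ny = y
            nz = z
    elif env == ENV_CONFINED:
        # corral cells of side L centered on the origin cell; a boundary
        # crossing is accepted (a hop) with probability p[1], else reflected
        L = p[0]
        p_hop = p[1]
        u3 = u1 + u2
        if u3 >= 1.0:
            u3 -= 1.0
        if np.floor((nx + 0.5 * L) / L) != np.floor((x + 0.5 * L) / L):
            if u1 >= p_hop:
                edge = L * (np.floor((x + 0.5 * L) / L)
                            + (1.0 if dx > 0 else 0.0)) - 0.5 * L
                nx = 2.0 * edge - nx
        if np.floor((ny + 0.5 * L) / L) != np.floor((y + 0.5 * L) / L):
            if u2 >= p_hop:
                edge = L * (np.floor((y + 0.5 * L) / L)
                            + (1.0 if dy > 0 else 0.0)) - 0.5 * L
                ny = 2.0 * edge - ny
        if np.floor((nz + 0.5 * L) / L) != np.floor((z + 0.5 * L) / L):
            if u3 >= p_hop:
                edge = L * (np.floor((z + 0.5 * L) / L)
                            + (1.0 if dz > 0 else 0.0)) - 0.5 * L
                nz = 2.0 * edge - nz
    # periodic wrap (x is reflective for the barrier environment)
    if env != ENV_BARRIER:
        if nx >= 0.5 * bx:
            nx -= bx
        elif nx < -0.5 * bx:
            nx += bx
    if ny >= 0.5 * by:
        ny -= by
    elif ny < -0.5 * by:
        ny += by
    if nz >= 0.5 * bz:
        nz -= bz
    elif nz < -0.5 * bz:
        nz += bz
    return nx, ny, nz


@njit(cache=True)
def walk_record(pos, steps, u, box, env, env_p, out):
    """Advance particles, recording every position into ``out`` (S, n, 3)."""
    S, n = steps.shape[0], steps.shape[1]
    for s in range(S):
        for i in range(n):
            x, y, z = _step_particle(
                pos[i, 0], pos[i, 1], pos[i, 2],
                steps[s, i, 0], steps[s, i, 1], steps[s, i, 2],
                u[s, i, 0], u[s, i, 1],
                box[0], box[1], box[2], env, env_p,
            )
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            out[s, i, 0] = x
            out[s, i, 1] = y
            out[s, i, 2] = z


@njit(cache=True, fastmath=True)
def render_positions(paths, det_x, det_y, inv_w2, inv_wz2, bright, rates):
    """Expected photon rates (S, C) for recorded positions (S, n, 3)."""
    S, n = paths.shape[0], paths.shape[1]
    C = det_x.size
    det_rmax = 0.0
    inv_w2_min = inv_w2[0]
    inv_wz2_min = inv_wz2[0]
    for c in range(C):
        r = np.sqrt(det_x[c] ** 2 + det_y[c] ** 2)
        if r > det_rmax:
            det_rmax = r
        if inv_w2[c] < inv_w2_min:
            inv_w2_min = inv_w2[c]
        if inv_wz2[c] < inv_wz2_min:
            inv_wz2_min = inv_wz2[c]
    for s in range(S):
        for i in range(n):
            x = paths[s, i, 0]
            y = paths[s, i, 1]
            z = paths[s, i, 2]
            rho = np.sqrt(x * x + y * y)
            d = rho - det_rmax
            if d < 0.0:
                d = 0.0
            if 2.0 * d * d * inv_w2_min + 2.0 * z * z * inv_wz2_min > _ARG_CUT:
                continue
            for c in range(C):
                ddx = x - det_x[c]
                ddy = y - det_y[c]
                arg = (
                    2.0 * (ddx * ddx + ddy * ddy) * inv_w2[c]
                    + 2.0 * z * z * inv_wz2[c]
                )
                if arg < _ARG_CUT:
                    rates[s, c] += bright[i] * np.exp(-arg)


@njit(cache=True, fastmath=True)
def walk_render(pos, steps, u, box, env, env_p,
                det_x, det_y, inv_w2, inv_wz2, bright, rates):
    """Fused walk + render (no stored positions); updates ``pos`` in place."""
    S, n = steps.shape[0], steps.shape[1]
    C = det_x.size
    det_rmax = 0.0
    inv_w2_min = inv_w2[0]
    inv_wz2_min = inv_wz2[0]
    for c in range(C):
        r = np.sqrt(det_x[c] ** 2 + det_y[c] ** 2)
        if r > det_rmax:
            det_rmax = r
        if inv_w2[c] < inv_w2_min:
            inv_w2_min = inv_w2[c]
        if inv_wz2[c] < inv_wz2_min:
            inv_wz2_min = inv_wz2[c]
    for s in range(S):
        for i in range(n):
            x, y, z = _step_particle(
                pos[i, 0], pos[i, 1], pos[i, 2],
                steps[s, i, 0], steps[s, i, 1], steps[s, i, 2],
                u[s, i, 0], u[s, i, 1],
                box[0], box[1], box[2], env, env_p,
            )
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            rho = np.sqrt(x * x + y * y)
            d = rho - det_rmax
            if d < 0.0:
                d = 0.0
            if 2.0 * d * d * inv_w2_min + 2.0 * z * z * inv_wz2_min > _ARG_CUT:
                continue
            for c in range(C):
                ddx = x - det_x[c]
                ddy = y - det_y[c]
                arg = (
                    2.0 * (ddx * ddx + ddy * ddy) * inv_w2[c]
                    + 2.0 * z * z * inv_wz2[c]
                )
                if arg < _ARG_CUT:
                    rates[s, c] += bright[i] * np.exp(-arg)
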
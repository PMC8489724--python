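"""Contact mechanics for 2D spherocylinders (numba kernels).

Cells are spherocylinders of width 1 um: a line segment of half-length
``hl = max(0, (l - w)/2)`` swept by a disc of radius w/2.  Two cells are in
contact when the minimum distance between their axis segments falls below the
cell width; the contact generates a linear (Hookean) repulsive force along the
line connecting the closest points, applied at the contact point so that it
also exerts a torque.  Positions and angles follow overdamped first-order
dynamics with drag proportional to cell length (translation) and length cubed
(rotation), and are relaxed quasi-statically after each growth increment until
the largest overlap falls below a tolerance or an iteration cap is reached.

The axial load ``F_axial`` reported for each cell is the sum over its contacts
of the inward-pointing component of the contact force along the cell axis,
halved (the average compressive load of the two poles) and normalized by the
cell length.  The normalization makes it a compressive axial stress proxy that
is comparable across strains of different mean length — the raw pole load
scales with how much column a cell happens to span, which would mask the
elevated lateral pushing of a shortened, disordered strain.  It serves as the
growth-expansion force proxy used in horizontal-force kymographs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

W_CELL = 1.0  # cell width, um


@njit(cache=True, fastmath=True)
def _segment_gap(px, py, ux, uy, h1, qx, qy, vx, vy, h2):
    """Closest points of two segments: returns (s, t, dx, dy, dist).

    Segment 1: p + s*u, s in [-h1, h1]; segment 2: q + t*v, t in [-h2, h2];
    (dx, dy) points from the point on 2 to the point on 1.
    """
    rx = px - qx
    ry = py - qy
    b = ux * vx + uy * vy
    e = ux * rx + uy * ry
    f = vx * rx + vy * ry
    denom = 1.0 - b * b
    if denom > 1e-9:
        s = (b * f - e) / denom
    else:
        s = -e  # near-parallel: start from the projection of q onto 1
    if s > h1:
        s = h1
    elif s < -h1:
        s = -h1
    # two clamped Gauss-Seidel passes
    for _ in range(2):
        t = f + s * b
        if t > h2:
            t = h2
        elif t < -h2:
            t = -h2
        s = t * b - e
        if s > h1:
            s = h1
        elif s < -h1:
            s = -h1
    t = f + s * b
    if t > h2:
        t = h2
    elif t < -h2:
        t = -h2
    dx = rx + s * ux - t * vx
    dy = ry + s * uy - t * vy
    return s, t, dx, dy, np.sqrt(dx * dx + dy * dy)


@njit(cache=True, fastmath=True)
def _build_pairs(x, y, hl, margin, pi_arr, pj_arr):
    """Broad-phase: indices of pairs whose bounding discs (+margin) overlap."""
    n = x.shape[0]
    m = 0
    cap = pi_arr.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            reach = hl[i] + hl[j] + W_CELL + margin
            if dx * dx + dy * dy < reach * reach:
                if m < cap:
                    pi_arr[m] = i
                    pj_arr[m] = j
                m += 1
    return m


@njit(cache=True, fastmath=True)
def relax_kernel(
    x, y, phi, length, hl,
    k_rep, zeta, zeta_rot, tol, max_iter, step_cap,
):
    """Relax overlaps in place; returns (F_axial, max_overlap, n_iter).

    k_rep: contact stiffness (force per um of overlap); zeta, zeta_rot: drag
    coefficients per unit length / length cubed; tol: residual overlap
    tolerance (um); step_cap: largest per-iteration displacement (um).
    """
    n = x.shape[0]
    f_ax = np.zeros(n)
    if n == 0:
        return f_ax, 0.0, 0
    cap = 32 * n + 64
    pi_arr = np.empty(cap, np.int64)
    pj_arr = np.empty(cap, np.int64)
    npairs = _build_pairs(x, y, hl, 1.0, pi_arr, pj_arr)
    if npairs > cap:
        npairs = cap
    fx = np.zeros(n)
    fy = np.zeros(n)
    tq = np.zeros(n)
    max_ov = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            fx[i] = 0.0
            fy[i] = 0.0
            tq[i] = 0.0
        max_ov = 0.0
        for p in range(npairs):
            i = pi_arr[p]
            j = pj_arr[p]
            ci = np.cos(phi[i]); si = np.sin(phi[i])
            cj = np.cos(phi[j]); sj = np.sin(phi[j])
            s, t, dx, dy, dist = _segment_gap(
                x[i], y[i], ci, si, hl[i], x[j], y[j], cj, sj, hl[j]
            )
            ov = W_CELL - dist
            if ov <= 0.0:
                continue
            if ov > max_ov:
                max_ov = ov
            if dist > 1e-9:
                nx_ = dx / dist
                ny_ = dy / dist
            else:
                # degenerate: push apart perpendicular to cell i's axis
                nx_ = -si
                ny_ = ci
            fmag = k_rep * ov
            fxp = fmag * nx_
            fyp = fmag * ny_
            fx[i] += fxp
            fy[i] += fyp
            fx[j] -= fxp
            fy[j] -= fyp
            # torque about each center from force at the contact point
            tq[i] += s * (ci * fyp - si * fxp)
            tq[j] -= t * (cj * fyp - sj * fxp)
        if max_ov < tol:
            break
        # overdamped update with an adaptive pseudo-time step
        vmax = 1e-30
        for i in range(n):
            mob = 1.0 / (zeta * length[i])
            vx = fx[i] * mob
            vy = fy[i] * mob
            om = tq[i] * 12.0 / (zeta_rot * length[i] ** 3)
            sp = np.sqrt(vx * vx + vy * vy) + abs(om) * hl[i]
            if sp > vmax:
                vmax = sp
        h = step_cap / vmax
        if h > 1.0:
            h = 1.0
        for i in range(n):
            mob = 1.0 / (zeta * length[i])
            x[i] += fx[i] * mob * h
            y[i] += fy[i] * mob * h
            phi[i] += tq[i] * 12.0 / (zeta_rot * length[i] ** 3) * h
    # final pass: compressive axial load per cell
    for p in range(npairs):
        i = pi_arr[p]
        j = pj_arr[p]
        ci = np.cos(phi[i]); si = np.sin(phi[i])
        cj = np.cos(phi[j]); sj = np.sin(phi[j])
        s, t, dx, dy, dist = _segment_gap(
            x[i], y[i], ci, si, hl[i], x[j], y[j], cj, sj, hl[j]
        )
        ov = W_CELL - dist
        if ov <= 0.0 or dist <= 1e-9:
            continue
        fmag = k_rep * ov
        fxp = fmag * dx / dist
        fyp = fmag * dy / dist
        ax_i = fxp * ci + fyp * si  # axial component of the force on i
        if s > 0.0 and ax_i < 0.0:
            f_ax[i] += -ax_i
        elif s < 0.0 and ax_i > 0.0:
            f_ax[i] += ax_i
        ax_j = -(fxp * cj + fyp * sj)  # force on j is -F
        if t > 0.0 and ax_j < 0.0:
            f_ax[j] += -ax_j
        elif t < 0.0 and ax_j > 0.0:
            f_ax[j] += ax_j
    for i in range(n):
        f_ax[i] *= 0.5 / length[i]
    return f_ax, max_ov, it
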
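"""Numba-compiled hot loops: exact stochastic simulation of the sheath
process, spherocylinder segment geometry, neighbor binning, and pairwise
contact forces.

All kernels are deterministic given their inputs (no fastmath, explicit
seeds).  Pure-Python reference implementations of the same geometry live in
:mod:`t6sim.mechanics` and serve as oracles in the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: direction fallback threshold for coincident axes (µm)
DEGENERATE_DIST = 1e-9


@njit(cache=True)
def ssa_sheath_ensemble(n, p0, tau, lam_plus, lam_s, lam_f, t_end, seed):
    """Exact (Gillespie) simulation of n independent two-stage reactors.

    Each reactor activates at time 0 with probability ``p0`` or at
    ``tau + Exp(lam_plus)`` otherwise, then runs the immigration--death
    sheath process (birth ``lam_s``, per-sheath death ``lam_f``) event by
    event until ``t_end``.  Returns the sheath count of every reactor.
    """
    np.random.seed(seed)
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if np.random.random() < p0:
            t_act = 0.0
        elif lam_plus > 0.0:
            t_act = tau + np.random.exponential(1.0 / lam_plus)
        else:
            t_act = np.inf
        count = 0
        t = t_act
        while t < t_end:
            rate = lam_s + lam_f * count
            if rate <= 0.0:
                break
            t += np.random.exponential(1.0 / rate)
            if t >= t_end:
                break
            if np.random.random() * rate < lam_s:
                count += 1
            else:
                count -= 1
        out[i] = count
    return out


@njit(cache=True)
def _closest_points(p0x, p0y, d1x, d1y, q0x, q0y, d2x, d2y):
    """Closest points between segments P0+s*d1 and Q0+t*d2, s,t in [0,1]."""
    rx = p0x - q0x
    ry = p0y - q0y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    eps = 1e-14
    if a <= eps and e <= eps:
        s = 0.0
        t = 0.0
    elif a <= eps:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry
        if e <= eps:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y
            denom = a * e - b * b
            if denom > eps:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    c1x = p0x + s * d1x
    c1y = p0y + s * d1y
    c2x = q0x + t * d2x
    c2y = q0y + t * d2y
    return c1x, c1y, c2x, c2y


def build_pairs(x, y, ux, uy, half, Lx, Ly, periodic, reach):
    """Interaction pairs (i < j) with axis-segment distance <= ``reach``.

    Uniform spatial binning prunes candidates by center distance, then the
    exact segment-segment distance decides membership, so the list holds
    every pair whose surface gap is within ``reach - 2*radius`` and little
    more.  Periodic arenas use the minimum-image convention; bins then tile
    the box exactly.  Falls back to an all-pairs sweep when the domain is
    too small to bin.
    """
    cap = 16 * x.size + 64
    pi, pj, m = _build_pairs_core(x, y, ux, uy, half, Lx, Ly, periodic, reach, cap)
    if m > cap:  # capacity guess too small; redo with the exact count
        pi, pj, m = _build_pairs_core(x, y, ux, uy, half, Lx, Ly, periodic, reach, m)
    return pi[:m].copy(), pj[:m].copy()


@njit(cache=True)
def _seg_dist(uxi, uyi, hi, dx, dy, uxj, uyj, hj):
    """Axis-segment distance between cell i (at origin) and cell j (at dx,dy)."""
    p0x = -hi * uxi
    p0y = -hi * uyi
    d1x = 2.0 * hi * uxi
    d1y = 2.0 * hi * uyi
    q0x = dx - hj * uxj
    q0y = dy - hj * uyj
    d2x = 2.0 * hj * uxj
    d2y = 2.0 * hj * uyj
    c1x, c1y, c2x, c2y = _closest_points(p0x, p0y, d1x, d1y, q0x, q0y, d2x, d2y)
    return np.sqrt((c1x - c2x) ** 2 + (c1y - c2y) ** 2)


@njit(cache=True)
def _build_pairs_core(x, y, ux, uy, half, Lx, Ly, periodic, reach, cap):
    n = x.size
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    hmax = 0.0
    for i in range(n):
        if half[i] > hmax:
            hmax = half[i]
    r_bound = 2.0 * hmax + reach  # max center distance of an admissible pair

    if periodic:
        x0 = 0.0
        y0 = 0.0
        ex = Lx
        ey = Ly
    else:
        xmin = x[0]
        xmax = x[0]
        ymin = y[0]
        ymax = y[0]
        for i in range(n):
            if x[i] < xmin:
                xmin = x[i]
            if x[i] > xmax:
                xmax = x[i]
            if y[i] < ymin:
                ymin = y[i]
            if y[i] > ymax:
                ymax = y[i]
        x0 = xmin - 1e-9
        y0 = ymin - 1e-9
        ex = (xmax - xmin) + 2e-9
        ey = (ymax - ymin) + 2e-9

    ncx = int(ex / r_bound) if r_bound > 0 else 0
    ncy = int(ey / r_bound) if r_bound > 0 else 0
    use_bins = ncx >= 3 and ncy >= 3 and n > 16
    if not use_bins:
        # brute force
        m = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx = x[j] - x[i]
                dy = y[j] - y[i]
                if periodic:
                    dx -= Lx * np.round(dx / Lx)
                    dy -= Ly * np.round(dy / Ly)
                cd = np.sqrt(dx * dx + dy * dy)
                if cd - half[i] - half[j] <= reach:
                    d = _seg_dist(
                        ux[i], uy[i], half[i], dx, dy, ux[j], uy[j], half[j]
                    )
                    if d <= reach:
                        if m < cap:
                            pi[m] = i
                            pj[m] = j
                        m += 1
        return pi, pj, m

    wx = ex / ncx
    wy = ey / ncy
    nbins = ncx * ncy
    head = np.full(nbins, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    binx = np.empty(n, dtype=np.int64)
    biny = np.empty(n, dtype=np.int64)
    for i in range(n):
        bx = int((x[i] - x0) / wx)
        by = int((y[i] - y0) / wy)
        if bx >= ncx:
            bx = ncx - 1
        if bx < 0:
            bx = 0
        if by >= ncy:
            by = ncy - 1
        if by < 0:
            by = 0
        binx[i] = bx
        biny[i] = by
        b = by * ncx + bx
        nxt[i] = head[b]
        head[b] = i

    m = 0
    for i in range(n):
        for oy in range(-1, 2):
            by = biny[i] + oy
            if periodic:
                by = by % ncy
            elif by < 0 or by >= ncy:
                continue
            for ox in range(-1, 2):
                bx = binx[i] + ox
                if periodic:
                    bx = bx % ncx
                elif bx < 0 or bx >= ncx:
                    continue
                j = head[by * ncx + bx]
                while j >= 0:
                    if j > i:
                        dx = x[j] - x[i]
                        dy = y[j] - y[i]
                        if periodic:
                            dx -= Lx * np.round(dx / Lx)
                            dy -= Ly * np.round(dy / Ly)
                        cd = np.sqrt(dx * dx + dy * dy)
                        if cd - half[i] - half[j] <= reach:
                            d = _seg_dist(
                                ux[i], uy[i], half[i], dx, dy, ux[j], uy[j], half[j]
                            )
                            if d <= reach:
                                if m < cap:
                                    pi[m] = i
                                    pj[m] = j
                                m += 1
                    j = nxt[j]
    return pi, pj, m


@njit(cache=True)
def build_csr(pi, pj, touch, n):
    """Symmetric CSR adjacency from the touching pairs (counting sort, O(m))."""
    deg = np.zeros(n, dtype=np.int64)
    for k in range(pi.size):
        if touch[k]:
            deg[pi[k]] += 1
            deg[pj[k]] += 1
    off = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        off[i + 1] = off[i] + deg[i]
    cursor = off[:n].copy()
    nbr = np.empty(off[n], dtype=np.int64)
    for k in range(pi.size):
        if touch[k]:
            nbr[cursor[pi[k]]] = pj[k]
            cursor[pi[k]] += 1
            nbr[cursor[pj[k]]] = pi[k]
            cursor[pj[k]] += 1
    return nbr, off, deg


@njit(cache=True)
def eval_pairs(
    pi,
    pj,
    x,
    y,
    ux,
    uy,
    half,
    radius,
    Lx,
    Ly,
    periodic,
    k_elastic,
    fx,
    fy,
    tq,
    ovl,
    gap,
):
    """Evaluate all candidate pairs: surface gaps, Hookean contact forces,
    torques about the cell centers, and per-cell overlap sums.

    ``fx, fy, tq, ovl`` are accumulated in place (caller zeroes them);
    ``gap[k]`` receives the surface gap of pair k (negative = overlap).
    Forces obey action--reaction exactly; coincident axes fall back to a
    deterministic push perpendicular to the lower-index cell's axis.
    """
    for k in range(pi.size):
        i = pi[k]
        j = pj[k]
        dx = x[j] - x[i]
        dy = y[j] - y[i]
        if periodic:
            dx -= Lx * np.round(dx / Lx)
            dy -= Ly * np.round(dy / Ly)
        # segment i in the frame of cell i's center
        p0x = -half[i] * ux[i]
        p0y = -half[i] * uy[i]
        d1x = 2.0 * half[i] * ux[i]
        d1y = 2.0 * half[i] * uy[i]
        q0x = dx - half[j] * ux[j]
        q0y = dy - half[j] * uy[j]
        d2x = 2.0 * half[j] * ux[j]
        d2y = 2.0 * half[j] * uy[j]
        c1x, c1y, c2x, c2y = _closest_points(p0x, p0y, d1x, d1y, q0x, q0y, d2x, d2y)
        ddx = c1x - c2x
        ddy = c1y - c2y
        d = np.sqrt(ddx * ddx + ddy * ddy)
        gap[k] = d - 2.0 * radius
        if d < 2.0 * radius:
            delta = 2.0 * radius - d
            if d > DEGENERATE_DIST:
                nx = ddx / d
                ny = ddy / d
            else:
                a = i if i < j else j
                nx = -uy[a]
                ny = ux[a]
            fmag = k_elastic * delta
            fxi = fmag * nx
            fyi = fmag * ny
            fx[i] += fxi
            fy[i] += fyi
            fx[j] -= fxi
            fy[j] -= fyi
            tq[i] += c1x * fyi - c1y * fxi
            tq[j] += (c2x - dx) * (-fyi) - (c2y - dy) * (-fxi)
            ovl[i] += delta
            ovl[j] += delta
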
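"""Numba kernels: neighbor search, pair/bond/angle forces, slab virials.

All kernels operate on plain float64/int64 arrays in reduced units and are
deterministic: the random pair force is generated by a counter-based
splitmix64 stream keyed on (seed, step, i, j) with i < j, so the noise a
pair receives is independent of iteration order and bitwise reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_SQRT12 = np.sqrt(12.0)  # uniform width giving unit variance
_TINY_R = 1.0e-10


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _pair_noise(base, i, j):
    """Unit-variance uniform deviate for unordered pair (i, j)."""
    lo = i if i < j else j
    hi = j if i < j else i
    key = base ^ ((np.uint64(lo) << np.uint64(32)) | np.uint64(hi))
    h = _mix64(key)
    u = (h >> np.uint64(11)) * (1.0 / 9007199254740992.0)  # [0, 1)
    return _SQRT12 * (u - 0.5)


@njit(cache=True)
def noise_base(seed, step):
    """Per-step stream base mixing the run seed and the step counter."""
    return _mix64((np.uint64(seed) << np.uint64(32)) ^ np.uint64(step))


@njit(cache=True, inline="always")
def _min_image(d, L):
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


# ---------------------------------------------------------------------------
# Neighbor search
# ---------------------------------------------------------------------------

@njit(cache=True)
def _count_pairs_brute(pos, box, rc):
    n = pos.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < rc * rc:
                count += 1
    return count


@njit(cache=True)
def _fill_pairs_brute(pos, box, rc, pi, pj):
    n = pos.shape[0]
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < rc * rc:
                pi[k] = i
                pj[k] = j
                k += 1
    return k


@njit(cache=True)
def _build_cells(pos, box, ncx, ncy, ncz):
    """Counting sort of beads into cells; returns (order, cell_start)."""
    n = pos.shape[0]
    ncell = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx)
        cy = int(pos[i, 1] / box[1] * ncy)
        cz = int(pos[i, 2] / box[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts.copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    return order, counts


@njit(cache=True)
def _cell_pairs(pos, box, rc, ncx, ncy, ncz, order, cell_start, pi, pj, count_only):
    """Iterate the half stencil of 13 neighbor cells + self once per pair."""
    k = 0
    rc2 = rc * rc
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0 = cell_start[c]
                a1 = cell_start[c + 1]
                # within-cell pairs
                for a in range(a0, a1):
                    i = order[a]
                    for b in range(a + 1, a1):
                        j = order[b]
                        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                        if dx * dx + dy * dy + dz * dz < rc2:
                            if not count_only:
                                pi[k] = i
                                pj[k] = j
                            k += 1
                # half stencil across cells
                for s in range(13):
                    ox, oy, oz = _HALF_STENCIL[s]
                    dcx = (cx + ox) % ncx
                    dcy = (cy + oy) % ncy
                    dcz = (cz + oz) % ncz
                    d = (dcx * ncy + dcy) * ncz + dcz
                    b0 = cell_start[d]
                    b1 = cell_start[d + 1]
                    for a in range(a0, a1):
                        i = order[a]
                        for b in range(b0, b1):
                            j = order[b]
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < rc2:
                                if not count_only:
                                    pi[k] = i
                                    pj[k] = j
                                k += 1
    return k


_HALF_STENCIL = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


def find_pairs(pos: np.ndarray, box: np.ndarray, rc: float):
    """Every unordered bead pair with minimum-image distance < rc, once.

    Uses a cell decomposition with edge >= rc when the box admits at least
    three cells per axis; otherwise falls back to the O(N^2) loop (the two
    agree exactly, which the test suite asserts on randomized boxes).
    Returns (i, j) int64 arrays.
    """
    # cell edge >= rc; more cells than ~one bead each gains nothing, so
    # cap the grid by bead count (relevant when rc is tiny)
    cap = max(3, int(np.ceil(pos.shape[0] ** (1.0 / 3.0))) + 1)
    ncx = min(int(box[0] / rc), cap)
    ncy = min(int(box[1] / rc), cap)
    ncz = min(int(box[2] / rc), cap)
    empty = np.empty(0, dtype=np.int64)
    if min(ncx, ncy, ncz) < 3 or pos.shape[0] < 64:
        n = _count_pairs_brute(pos, box, rc)
        pi = np.empty(n, dtype=np.int64)
        pj = np.empty(n, dtype=np.int64)
        _fill_pairs_brute(pos, box, rc, pi, pj)
        return pi, pj
    order, cell_start = _build_cells(pos, box, ncx, ncy, ncz)
    n = _cell_pairs(pos, box, rc, ncx, ncy, ncz, order, cell_start,
                    empty, empty, True)
    pi = np.empty(n, dtype=np.int64)
    pj = np.empty(n, dtype=np.int64)
    _cell_pairs(pos, box, rc, ncx, ncy, ncz, order, cell_start, pi, pj, False)
    return pi, pj


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def pair_forces(pos, vel, species, pi, pj, box, a_table, rc,
                gamma, sigma, inv_sqrt_dt, base, forces, virial):
    """Conservative + dissipative + random DPD pair forces.

    Accumulates into ``forces`` (N, 3); adds the conservative-only diagonal
    virial sum(F_a * d_a) into ``virial`` (3,).  Returns the conservative
    pair potential energy.
    """
    epot = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r >= rc:
            continue
        if r < _TINY_R:
            # overlapping beads: deterministic fallback direction
            r = _TINY_R
            dx, dy, dz = _TINY_R, 0.0, 0.0
        inv_r = 1.0 / r
        ex = dx * inv_r
        ey = dy * inv_r
        ez = dz * inv_r
        w = 1.0 - r / rc
        a = a_table[species[i], species[j]]
        fc = a * w
        epot += 0.5 * a * rc * w * w
        # conservative virial (per-axis diagonal)
        virial[0] += fc * ex * dx
        virial[1] += fc * ey * dy
        virial[2] += fc * ez * dz
        ftot = fc
        if gamma > 0.0 or sigma > 0.0:
            dvx = vel[i, 0] - vel[j, 0]
            dvy = vel[i, 1] - vel[j, 1]
            dvz = vel[i, 2] - vel[j, 2]
            vdote = dvx * ex + dvy * ey + dvz * ez
            ftot += -gamma * w * w * vdote
            if sigma > 0.0:
                zeta = _pair_noise(base, i, j)
                ftot += sigma * w * zeta * inv_sqrt_dt
        forces[i, 0] += ftot * ex
        forces[i, 1] += ftot * ey
        forces[i, 2] += ftot * ez
        forces[j, 0] -= ftot * ex
        forces[j, 1] -= ftot * ey
        forces[j, 2] -= ftot * ez
    return epot


@njit(cache=True)
def bond_forces(pos, bond_ij, bond_ks, bond_rs, box, forces, virial):
    """Harmonic bonds F = ks (1 - r/rs) rhat; returns the bond energy.

    The potential is U = ks/(2 rs) (r - rs)^2, the antiderivative of the
    stated force.  Coincident bonded beads fall back to a deterministic
    x-axis direction.
    """
    epot = 0.0
    for k in range(bond_ij.shape[0]):
        i = bond_ij[k, 0]
        j = bond_ij[k, 1]
        ks = bond_ks[k]
        rs = bond_rs[k]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _TINY_R:
            r = _TINY_R
            dx, dy, dz = _TINY_R, 0.0, 0.0
        inv_r = 1.0 / r
        f = ks * (1.0 - r / rs)
        epot += 0.5 * ks / rs * (r - rs) * (r - rs)
        fx = f * dx * inv_r
        fy = f * dy * inv_r
        fz = f * dz * inv_r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz
    return epot


@njit(cache=True)
def angle_forces(pos, angle_ijk, angle_k, angle_t0, box, forces, virial):
    """Harmonic bending U = k (theta - theta0)^2; returns the angle energy.

    Gradient is exact except within 1e-8 of the sin(theta)=0 poles, where
    the sine is clamped to keep the force finite.
    """
    epot = 0.0
    for t in range(angle_ijk.shape[0]):
        i = angle_ijk[t, 0]
        j = angle_ijk[t, 1]  # vertex
        k = angle_ijk[t, 2]
        kth = angle_k[t]
        t0 = angle_t0[t]
        ux = _min_image(pos[i, 0] - pos[j, 0], box[0])
        uy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        uz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        wx = _min_image(pos[k, 0] - pos[j, 0], box[0])
        wy = _min_image(pos[k, 1] - pos[j, 1], box[1])
        wz = _min_image(pos[k, 2] - pos[j, 2], box[2])
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if nu < _TINY_R or nw < _TINY_R:
            continue
        c = (ux * wx + uy * wy + uz * wz) / (nu * nw)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - t0
        epot += kth * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            s = 1.0e-8
        coef = 2.0 * kth * dth / s
        # d cos(theta) / d r_i and d r_k
        gix = coef * (wx / (nu * nw) - c * ux / (nu * nu))
        giy = coef * (wy / (nu * nw) - c * uy / (nu * nu))
        giz = coef * (wz / (nu * nw) - c * uz / (nu * nu))
        gkx = coef * (ux / (nu * nw) - c * wx / (nw * nw))
        gky = coef * (uy / (nu * nw) - c * wy / (nw * nw))
        gkz = coef * (uz / (nu * nw) - c * wz / (nw * nw))
        forces[i, 0] += gix
        forces[i, 1] += giy
        forces[i, 2] += giz
        forces[k, 0] += gkx
        forces[k, 1] += gky
        forces[k, 2] += gkz
        forces[j, 0] -= gix + gkx
        forces[j, 1] -= giy + gky
        forces[j, 2] -= giz + gkz
        # pairwise decomposition (i,j) and (k,j) for the virial
        virial[0] += gix * ux + gkx * wx
        virial[1] += giy * uy + gky * wy
        virial[2] += giz * uz + gkz * wz
    return epot


# ---------------------------------------------------------------------------
# Slab-resolved (Irving-Kirkwood) virials for pressure profiles
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _wrap(z, L):
    z = z % L
    if z < 0.0:
        z += L
    return z


@njit(cache=True)
def _ik_deposit(z_from, dz_seg, Lz, n_slabs, vx, vy, vz, out):
    """Distribute a pair-virial contribution over slabs along the i-j segment.

    ``z_from`` is the wrapped z of one endpoint, ``dz_seg`` the minimum-image
    z displacement to the other.  Weights are segment-length fractions per
    slab, so the slab sum reproduces the unsliced virial exactly.
    """
    h = Lz / n_slabs
    if abs(dz_seg) < 1.0e-12:
        s = int(_wrap(z_from, Lz) / h)
        if s >= n_slabs:
            s = n_slabs - 1
        out[s, 0] += vx
        out[s, 1] += vy
        out[s, 2] += vz
        return
    a = z_from
    b = z_from + dz_seg
    if b < a:
        a, b = b, a
    span = b - a
    sa = int(np.floor(a / h))
    sb = int(np.floor(b / h))
    for s in range(sa, sb + 1):
        lo = a if a > s * h else s * h
        hi = b if b < (s + 1) * h else (s + 1) * h
        if hi <= lo:
            continue
        w = (hi - lo) / span
        sw = s % n_slabs
        if sw < 0:
            sw += n_slabs
        out[sw, 0] += w * vx
        out[sw, 1] += w * vy
        out[sw, 2] += w * vz


@njit(cache=True)
def slab_pair_virial(pos, pi, pj, species, a_table, box, rc, n_slabs, out):
    """Conservative pair-force virial distributed over z-slabs."""
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= rc or r < _TINY_R:
            continue
        a = a_table[species[i], species[j]]
        f_over_r = a * (1.0 - r / rc) / r
        vx = f_over_r * dx * dx
        vy = f_over_r * dy * dy
        vz = f_over_r * dz * dz
        _ik_deposit(_wrap(pos[j, 2], box[2]), dz, box[2], n_slabs,
                    vx, vy, vz, out)


@njit(cache=True)
def slab_bond_virial(pos, bond_ij, bond_ks, bond_rs, box, n_slabs, out):
    for k in range(bond_ij.shape[0]):
        i = bond_ij[k, 0]
        j = bond_ij[k, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _TINY_R:
            continue
        f_over_r = bond_ks[k] * (1.0 - r / bond_rs[k]) / r
        vx = f_over_r * dx * dx
        vy = f_over_r * dy * dy
        vz = f_over_r * dz * dz
        _ik_deposit(_wrap(pos[j, 2], box[2]), dz, box[2], n_slabs,
                    vx, vy, vz, out)


@njit(cache=True)
def slab_angle_virial(pos, angle_ijk, angle_k, angle_t0, box, n_slabs, out):
    """Angle-force virial, decomposed into (i,vertex) and (k,vertex) pairs."""
    for t in range(angle_ijk.shape[0]):
        i = angle_ijk[t, 0]
        j = angle_ijk[t, 1]
        k = angle_ijk[t, 2]
        kth = angle_k[t]
        t0 = angle_t0[t]
        ux = _min_image(pos[i, 0] - pos[j, 0], box[0])
        uy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        uz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        wx = _min_image(pos[k, 0] - pos[j, 0], box[0])
        wy = _min_image(pos[k, 1] - pos[j, 1], box[1])
        wz = _min_image(pos[k, 2] - pos[j, 2], box[2])
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if nu < _TINY_R or nw < _TINY_R:
            continue
        c = (ux * wx + uy * wy + uz * wz) / (nu * nw)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            s = 1.0e-8
        coef = 2.0 * kth * (theta - t0) / s
        gix = coef * (wx / (nu * nw) - c * ux / (nu * nu))
        giy = coef * (wy / (nu * nw) - c * uy / (nu * nu))
        giz = coef * (wz / (nu * nw) - c * uz / (nu * nu))
        gkx = coef * (ux / (nu * nw) - c * wx / (nw * nw))
        gky = coef * (uy / (nu * nw) - c * wy / (nw * nw))
        gkz = coef * (uz / (nu * nw) - c * wz / (nw * nw))
        zj = _wrap(pos[j, 2], box[2])
        _ik_deposit(zj, uz, box[2], n_slabs,
                    gix * ux, giy * uy, giz * uz, out)
        _ik_deposit(zj, wz, box[2], n_slabs,
                    gkx * wx, gky * wy, gkz * wz, out)
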
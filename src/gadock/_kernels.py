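"""Numba kernels for the scoring hot loop.

Each kernel is the compiled twin of a closed-form term defined in
:mod:`gadock.scoring`; unit tests assert agreement with the pure-Python
forms.  ``cache=True`` persists compilation across processes.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["vdw_sum", "pair_vdw_sum", "polar_attract", "polar_repulse",
           "cavity_sq_dist_sum"]


@njit(cache=True, fastmath=False)
def vdw_sum(lig, rec, r0, eps, m, cap):
    """Capped n-m pair sum over a ligand x receptor distance matrix."""
    total = 0.0
    for i in range(lig.shape[0]):
        xi, yi, zi = lig[i, 0], lig[i, 1], lig[i, 2]
        for j in range(rec.shape[0]):
            dx = xi - rec[j, 0]
            dy = yi - rec[j, 1]
            dz = zi - rec[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-6:
                r = 1e-6
            x = (r0[i, j] / r) ** m
            e = eps[i, j] * (x * x - 2.0 * x)
            total += e if e < cap else cap
    return total


@njit(cache=True, fastmath=False)
def pair_vdw_sum(coords, ii, jj, r0, eps, scale, m, cap):
    """Capped n-m sum over an explicit (1-4 scaled) intra pair list."""
    total = 0.0
    for k in range(ii.shape[0]):
        i, j = ii[k], jj[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-6:
            r = 1e-6
        x = (r0[k] / r) ** m
        e = eps[k] * (x * x - 2.0 * x)
        total += scale[k] * (e if e < cap else cap)
    return total


@njit(cache=True, fastmath=False)
def _angle_deg(ax, ay, az, bx, by, bz):
    num = ax * bx + ay * by + az * bz
    den = math.sqrt((ax * ax + ay * ay + az * az)
                    * (bx * bx + by * by + bz * bz)) + 1e-12
    c = num / den
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.degrees(math.acos(c))


@njit(cache=True, fastmath=False)
def _ramp_above(x, lo, tol):
    v = (x - (lo - tol)) / tol
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=True, fastmath=False)
def _ramp_window(x, lo, hi, tol):
    up = (x - (lo - tol)) / tol
    dn = ((hi + tol) - x) / tol
    v = up if up < dn else dn
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=True, fastmath=False)
def polar_attract(D, H, dflag, A, R, has_root, aflag, mask,
                  lo, hi, dtol, don_lo, acc_lo, atol, well, cm):
    """Donor->acceptor sum of -W*mult*f_dist*f_donor_angle*f_acceptor_angle.

    ``mask`` is an (nd, na) 0/1 pair filter (pass an all-ones array when no
    filter applies).
    """
    total = 0.0
    cut = hi + dtol
    for i in range(D.shape[0]):
        for j in range(A.shape[0]):
            if mask[i, j] == 0.0:
                continue
            dx = D[i, 0] - A[j, 0]
            dy = D[i, 1] - A[j, 1]
            dz = D[i, 2] - A[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d > cut or d < 1e-6:
                continue
            f = _ramp_window(d, lo, hi, dtol)
            if f == 0.0:
                continue
            th = _angle_deg(D[i, 0] - H[i, 0], D[i, 1] - H[i, 1],
                            D[i, 2] - H[i, 2],
                            A[j, 0] - H[i, 0], A[j, 1] - H[i, 1],
                            A[j, 2] - H[i, 2])
            f *= _ramp_above(th, don_lo, atol)
            if f == 0.0:
                continue
            if has_root[j]:
                ph = _angle_deg(H[i, 0] - A[j, 0], H[i, 1] - A[j, 1],
                                H[i, 2] - A[j, 2],
                                R[j, 0] - A[j, 0], R[j, 1] - A[j, 1],
                                R[j, 2] - A[j, 2])
                f *= _ramp_above(ph, acc_lo, atol)
            total -= well * (cm ** (dflag[i] + aflag[j])) * f
    return total


@njit(cache=True, fastmath=False)
def polar_repulse(Xa, fa, Xb, fb, lo, hi, dtol, rep, cm):
    """Distance-only same-class clash term (donor-donor, acceptor-acceptor)."""
    total = 0.0
    cut = hi + dtol
    for i in range(Xa.shape[0]):
        for j in range(Xb.shape[0]):
            dx = Xa[i, 0] - Xb[j, 0]
            dy = Xa[i, 1] - Xb[j, 1]
            dz = Xa[i, 2] - Xb[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d > cut:
                continue
            total += rep * (cm ** (fa[i] + fb[j])) * _ramp_window(d, lo, hi, dtol)
    return total


@njit(cache=True, fastmath=False)
def cavity_sq_dist_sum(atoms, points, half_spacing):
    """Sum over atoms of squared distance to the nearest cavity point
    (zero within half a grid spacing), by exact brute-force search."""
    total = 0.0
    h2 = half_spacing * half_spacing
    for i in range(atoms.shape[0]):
        best = 1e30
        for j in range(points.shape[0]):
            dx = atoms[i, 0] - points[j, 0]
            dy = atoms[i, 1] - points[j, 1]
            dz = atoms[i, 2] - points[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
                if best <= h2:
                    break
        if best > h2:
            total += best
    return total


@njit(cache=True, fastmath=False)
def polar_total(lig, rec, ld_h, ld_r, ld_f, la_a, la_r, la_has, la_f,
                rd_h, rd_r, rd_f, ra_a, ra_r, ra_has, ra_f,
                lo, hi, dtol, don_lo, acc_lo, atol, well, cm,
                rep, repulsive_on):
    """Full intermolecular polar term: ligand-donor x receptor-acceptor and
    receptor-donor x ligand-acceptor attractive sums, plus donor-donor and
    acceptor-acceptor clashes when ``repulsive_on``."""
    total = 0.0
    cut = hi + dtol
    # ligand donors -> receptor acceptors
    for i in range(ld_h.shape[0]):
        hh, rr = ld_h[i], ld_r[i]
        for j in range(ra_a.shape[0]):
            aa = ra_a[j]
            dx = lig[rr, 0] - rec[aa, 0]
            dy = lig[rr, 1] - rec[aa, 1]
            dz = lig[rr, 2] - rec[aa, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d > cut or d < 1e-6:
                continue
            f = _ramp_window(d, lo, hi, dtol)
            th = _angle_deg(lig[rr, 0] - lig[hh, 0], lig[rr, 1] - lig[hh, 1],
                            lig[rr, 2] - lig[hh, 2],
                            rec[aa, 0] - lig[hh, 0], rec[aa, 1] - lig[hh, 1],
                            rec[aa, 2] - lig[hh, 2])
            f *= _ramp_above(th, don_lo, atol)
            if f == 0.0:
                continue
            if ra_has[j]:
                qq = ra_r[j]
                ph = _angle_deg(lig[hh, 0] - rec[aa, 0],
                                lig[hh, 1] - rec[aa, 1],
                                lig[hh, 2] - rec[aa, 2],
                                rec[qq, 0] - rec[aa, 0],
                                rec[qq, 1] - rec[aa, 1],
                                rec[qq, 2] - rec[aa, 2])
                f *= _ramp_above(ph, acc_lo, atol)
            total -= well * (cm ** (ld_f[i] + ra_f[j])) * f
    # receptor donors -> ligand acceptors
    for i in range(rd_h.shape[0]):
        hh, rr = rd_h[i], rd_r[i]
        for j in range(la_a.shape[0]):
            aa = la_a[j]
            dx = rec[rr, 0] - lig[aa, 0]
            dy = rec[rr, 1] - lig[aa, 1]
            dz = rec[rr, 2] - lig[aa, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d > cut or d < 1e-6:
                continue
            f = _ramp_window(d, lo, hi, dtol)
            th = _angle_deg(rec[rr, 0] - rec[hh, 0], rec[rr, 1] - rec[hh, 1],
                            rec[rr, 2] - rec[hh, 2],
                            lig[aa, 0] - rec[hh, 0], lig[aa, 1] - rec[hh, 1],
                            lig[aa, 2] - rec[hh, 2])
            f *= _ramp_above(th, don_lo, atol)
            if f == 0.0:
                continue
            if la_has[j]:
                qq = la_r[j]
                ph = _angle_deg(rec[hh, 0] - lig[aa, 0],
                                rec[hh, 1] - lig[aa, 1],
                                rec[hh, 2] - lig[aa, 2],
                                lig[qq, 0] - lig[aa, 0],
                                lig[qq, 1] - lig[aa, 1],
                                lig[qq, 2] - lig[aa, 2])
                f *= _ramp_above(ph, acc_lo, atol)
            total -= well * (cm ** (rd_f[i] + la_f[j])) * f
    if repulsive_on:
        for i in range(ld_r.shape[0]):
            for j in range(rd_r.shape[0]):
                dx = lig[ld_r[i], 0] - rec[rd_r[j], 0]
                dy = lig[ld_r[i], 1] - rec[rd_r[j], 1]
                dz = lig[ld_r[i], 2] - rec[rd_r[j], 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d <= cut:
                    total += rep * (cm ** (ld_f[i] + rd_f[j])) \
                        * _ramp_window(d, lo, hi, dtol)
        for i in range(la_a.shape[0]):
            for j in range(ra_a.shape[0]):
                dx = lig[la_a[i], 0] - rec[ra_a[j], 0]
                dy = lig[la_a[i], 1] - rec[ra_a[j], 1]
                dz = lig[la_a[i], 2] - rec[ra_a[j], 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d <= cut:
                    total += rep * (cm ** (la_f[i] + ra_f[j])) \
                        * _ramp_window(d, lo, hi, dtol)
    return total


@njit(cache=True, fastmath=False)
def cavity_sq_dist_sum_lattice(atoms, inside, origin, spacing, half_spacing):
    """Sum of squared distances to the nearest inside lattice point, by an
    expanding Chebyshev-shell search over the boolean cavity lattice.

    Exact: shells keep expanding until no closer Euclidean point can exist.
    Zero within half a spacing of an inside point.
    """
    nx, ny, nz = inside.shape
    h2 = half_spacing * half_spacing
    total = 0.0
    for k in range(atoms.shape[0]):
        px = (atoms[k, 0] - origin[0]) / spacing
        py = (atoms[k, 1] - origin[1]) / spacing
        pz = (atoms[k, 2] - origin[2]) / spacing
        cx = int(round(px))
        cy = int(round(py))
        cz = int(round(pz))
        best = 1.0e30
        # shells must reach the far side of the lattice even from a distant
        # query point
        gap = 0
        if cx < 0:
            gap = max(gap, -cx)
        elif cx > nx - 1:
            gap = max(gap, cx - (nx - 1))
        if cy < 0:
            gap = max(gap, -cy)
        elif cy > ny - 1:
            gap = max(gap, cy - (ny - 1))
        if cz < 0:
            gap = max(gap, -cz)
        elif cz > nz - 1:
            gap = max(gap, cz - (nz - 1))
        rmax = gap + nx + ny + nz + 2
        for r in range(rmax):
            # stop once the closest possible point in this shell cannot beat
            # the current best
            if best < 1.0e29:
                dmin_shell = (r - 1) * spacing  # conservative lower bound
                if dmin_shell > 0 and dmin_shell * dmin_shell > best:
                    break
            x0, x1 = cx - r, cx + r
            y0, y1 = cy - r, cy + r
            z0, z1 = cz - r, cz + r
            for ix in range(max(0, x0), min(nx, x1 + 1)):
                on_x = ix == x0 or ix == x1
                for iy in range(max(0, y0), min(ny, y1 + 1)):
                    on_y = iy == y0 or iy == y1
                    for iz in range(max(0, z0), min(nz, z1 + 1)):
                        if not (on_x or on_y or iz == z0 or iz == z1):
                            continue
                        if not inside[ix, iy, iz]:
                            continue
                        dx = (px - ix) * spacing
                        dy = (py - iy) * spacing
                        dz = (pz - iz) * spacing
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 < best:
                            best = d2
        if best > h2 and best < 1.0e29:
            total += best
    return total


@njit(cache=True, fastmath=False)
def apply_torsions(coords, b_arr, c_arr, idx_flat, idx_off, deltas):
    """Apply a sequence of torsion rotations in place.

    For torsion k, rotates the atoms ``idx_flat[idx_off[k]:idx_off[k+1]]``
    about the axis from atom ``b_arr[k]`` to ``c_arr[k]`` so the measured
    dihedral increases by ``deltas[k]`` (same sign convention as
    ``model.apply_dihedral``).
    """
    for k in range(b_arr.shape[0]):
        b = b_arr[k]
        c = c_arr[k]
        ax = coords[c, 0] - coords[b, 0]
        ay = coords[c, 1] - coords[b, 1]
        az = coords[c, 2] - coords[b, 2]
        n = math.sqrt(ax * ax + ay * ay + az * az)
        if n < 1e-12:
            continue
        ax /= n
        ay /= n
        az /= n
        t = -math.radians(deltas[k])
        ct = math.cos(t)
        st = math.sin(t)
        one_ct = 1.0 - ct
        r00 = ct + ax * ax * one_ct
        r01 = ax * ay * one_ct - az * st
        r02 = ax * az * one_ct + ay * st
        r10 = ay * ax * one_ct + az * st
        r11 = ct + ay * ay * one_ct
        r12 = ay * az * one_ct - ax * st
        r20 = az * ax * one_ct - ay * st
        r21 = az * ay * one_ct + ax * st
        r22 = ct + az * az * one_ct
        bx = coords[b, 0]
        by = coords[b, 1]
        bz = coords[b, 2]
        for q in range(idx_off[k], idx_off[k + 1]):
            i = idx_flat[q]
            vx = coords[i, 0] - bx
            vy = coords[i, 1] - by
            vz = coords[i, 2] - bz
            coords[i, 0] = r00 * vx + r01 * vy + r02 * vz + bx
            coords[i, 1] = r10 * vx + r11 * vy + r12 * vz + by
            coords[i, 2] = r20 * vx + r21 * vy + r22 * vz + bz
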
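"""Low-level numba kernels: analytic triangle potentials and Galerkin loops.

All integrals here are over flat triangles with the raw Newton kernel
``1/||x - r'||`` (the ``1/(4*pi)`` normalisation is applied by callers).
The closed forms are the classical edge-based expressions: for observation
point ``x`` with signed height ``h`` above the triangle plane and in-plane
projection ``rho``,

    K1  = int_T 1/R dS'            = sum_i t_i f2_i - |h| |Omega|
    Iv1 = int_T (r'-rho)/R dS'     = sum_i m_i (R0_i^2 f2_i + s+R+ - s-R-)/2
    Iv3 = int_T (r'-rho)/R^3 dS'   = -sum_i m_i f2_i
    Omega = int_T n.(r'-x)/R^3 dS'   (signed solid angle, van Oosterom)

where ``f2_i = log((R+ + s+)/(R- + s-))`` is the edge line integral of 1/R,
``t_i`` the signed in-plane distance of rho to edge i and ``m_i`` the
in-plane outward edge normal.  Linear (P1) densities are affine in-plane, so
every needed single/double-layer inner integral reduces to the above.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "solid_angles_sum",
    "triangle_precompute",
    "gauss_rule",
    "galerkin_ss",
    "galerkin_d",
    "point_sd",
    "dipole_p0_integrals",
    "dipole_p1_integrals",
]


# ---------------------------------------------------------------------------
# quadrature rules on the reference triangle (barycentric coords, weights
# normalised to sum to 1; multiply by the triangle area)
# ---------------------------------------------------------------------------

def gauss_rule(n_points: int = 7):
    """Symmetric Gauss rules on a triangle: 1 (degree 1), 3 (degree 2) or
    7 points (degree 5)."""
    if n_points == 1:
        b = np.array([[1 / 3, 1 / 3, 1 / 3]])
        w = np.array([1.0])
    elif n_points == 3:
        b = np.array([[2 / 3, 1 / 6, 1 / 6],
                      [1 / 6, 2 / 3, 1 / 6],
                      [1 / 6, 1 / 6, 2 / 3]])
        w = np.full(3, 1 / 3)
    elif n_points == 7:
        s15 = math.sqrt(15.0)
        a1, b1 = (6 + s15) / 21, (9 - 2 * s15) / 21
        a2, b2 = (6 - s15) / 21, (9 + 2 * s15) / 21
        w1, w2 = (155 + s15) / 1200, (155 - s15) / 1200
        b = np.array([
            [1 / 3, 1 / 3, 1 / 3],
            [b1, a1, a1], [a1, b1, a1], [a1, a1, b1],
            [b2, a2, a2], [a2, b2, a2], [a2, a2, b2],
        ])
        w = np.array([9 / 40, w1, w1, w1, w2, w2, w2])
    else:
        raise ValueError("supported rules: 1, 3 or 7 points")
    return np.ascontiguousarray(b), np.ascontiguousarray(w)


def triangle_precompute(mesh):
    """Per-triangle geometry pack for the analytic kernels.

    Returns (corners (nt,3,3), shat (nt,3,3), mhat (nt,3,3), nhat (nt,3),
    grads (nt,3,3) in-plane P1 gradients, scale (nt,)).
    """
    p0, p1, p2 = mesh.corners
    corners = np.stack([p0, p1, p2], axis=1)
    e = np.stack([p1 - p0, p2 - p1, p0 - p2], axis=1)  # edge i: from v_i
    elen = np.linalg.norm(e, axis=2, keepdims=True)
    shat = e / elen
    n = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(n, axis=1, keepdims=True)
    nhat = n / a2
    mhat = np.cross(shat, nhat[:, None, :])
    # in-plane gradient of P1 shape function j: nhat x (opposite edge)/(2A)
    opp = np.stack([p2 - p1, p0 - p2, p1 - p0], axis=1)
    grads = np.cross(nhat[:, None, :], opp) / a2[:, :, None]
    scale = elen[:, :, 0].max(axis=1)
    return (np.ascontiguousarray(corners), np.ascontiguousarray(shat),
            np.ascontiguousarray(mhat), np.ascontiguousarray(nhat),
            np.ascontiguousarray(grads), np.ascontiguousarray(scale))


# ---------------------------------------------------------------------------
# scalar analytic building blocks
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _vos_solid_angle(ax, ay, az, bx, by, bz, cx, cy, cz):
    """Signed solid angle of a triangle seen from the origin (van Oosterom &
    Strackee); positive when the vertex order appears counter-clockwise."""
    la = math.sqrt(ax * ax + ay * ay + az * az)
    lb = math.sqrt(bx * bx + by * by + bz * bz)
    lc = math.sqrt(cx * cx + cy * cy + cz * cz)
    num = (ax * (by * cz - bz * cy) + ay * (bz * cx - bx * cz)
           + az * (bx * cy - by * cx))
    den = (la * lb * lc + (ax * bx + ay * by + az * bz) * lc
           + (bx * cx + by * cy + bz * cz) * la
           + (cx * ax + cy * ay + cz * az) * lb)
    return 2.0 * math.atan2(num, den)


@njit(cache=True, fastmath=True)
def solid_angles_sum(points, p0, p1, p2):
    """Sum over all triangles of the signed solid angle at each point."""
    npts = points.shape[0]
    nt = p0.shape[0]
    out = np.zeros(npts)
    for i in range(npts):
        x, y, z = points[i, 0], points[i, 1], points[i, 2]
        acc = 0.0
        for k in range(nt):
            acc += _vos_solid_angle(
                p0[k, 0] - x, p0[k, 1] - y, p0[k, 2] - z,
                p1[k, 0] - x, p1[k, 1] - y, p1[k, 2] - z,
                p2[k, 0] - x, p2[k, 1] - y, p2[k, 2] - z)
        out[i] = acc
    return out


@njit(cache=True, inline="always", fastmath=True)
def _edge_f2(R1, s1, R2, s2):
    """Stable log((R2+s2)/(R1+s1)) = integral of 1/R along an edge."""
    d1 = R1 + s1
    d2 = R2 - s2
    if d1 > d2:  # use the forward branch
        den = d1
        num = R2 + s2
    else:        # backward branch avoids cancellation when s < 0
        den = d2
        num = R1 - s1
    if den <= 0.0 or num <= 0.0:
        return 0.0  # observation point on the edge line: users multiply by 0
    return math.log(num / den)


@njit(cache=True, inline="always", fastmath=True)
def _analytic_S(xx, xy, xz, corners, shat, mhat, nhat, k):
    """K1 = int_T 1/R dS' for one triangle k of a precomputed pack."""
    nx, ny, nz = nhat[k, 0], nhat[k, 1], nhat[k, 2]
    dx = xx - corners[k, 0, 0]
    dy = xy - corners[k, 0, 1]
    dz = xz - corners[k, 0, 2]
    h = dx * nx + dy * ny + dz * nz
    rx, ry, rz = xx - h * nx, xy - h * ny, xz - h * nz  # projection rho
    k1 = 0.0
    for e in range(3):
        e2 = (e + 1) % 3
        px = corners[k, e, 0] - rx
        py = corners[k, e, 1] - ry
        pz = corners[k, e, 2] - rz
        qx = corners[k, e2, 0] - rx
        qy = corners[k, e2, 1] - ry
        qz = corners[k, e2, 2] - rz
        t = px * mhat[k, e, 0] + py * mhat[k, e, 1] + pz * mhat[k, e, 2]
        s1 = px * shat[k, e, 0] + py * shat[k, e, 1] + pz * shat[k, e, 2]
        s2 = qx * shat[k, e, 0] + qy * shat[k, e, 1] + qz * shat[k, e, 2]
        R1 = math.sqrt(px * px + py * py + pz * pz + h * h)
        R2 = math.sqrt(qx * qx + qy * qy + qz * qz + h * h)
        k1 += t * _edge_f2(R1, s1, R2, s2)
    om = _vos_solid_angle(
        corners[k, 0, 0] - xx, corners[k, 0, 1] - xy, corners[k, 0, 2] - xz,
        corners[k, 1, 0] - xx, corners[k, 1, 1] - xy, corners[k, 1, 2] - xz,
        corners[k, 2, 0] - xx, corners[k, 2, 1] - xy, corners[k, 2, 2] - xz)
    return k1 - abs(h) * abs(om)


@njit(cache=True, inline="always", fastmath=True)
def _analytic_D(xx, xy, xz, corners, shat, mhat, nhat, grads, scale, k):
    """(int_T dG/dn' phi_j dS') * 4*pi for the three local P1 functions.

    Principal-value convention: coplanar observation points contribute 0.
    """
    nx, ny, nz = nhat[k, 0], nhat[k, 1], nhat[k, 2]
    dx = xx - corners[k, 0, 0]
    dy = xy - corners[k, 0, 1]
    dz = xz - corners[k, 0, 2]
    h = dx * nx + dy * ny + dz * nz
    if abs(h) < 1e-12 * scale[k]:
        return 0.0, 0.0, 0.0
    rx, ry, rz = xx - h * nx, xy - h * ny, xz - h * nz
    i3x = 0.0
    i3y = 0.0
    i3z = 0.0
    for e in range(3):
        e2 = (e + 1) % 3
        px = corners[k, e, 0] - rx
        py = corners[k, e, 1] - ry
        pz = corners[k, e, 2] - rz
        qx = corners[k, e2, 0] - rx
        qy = corners[k, e2, 1] - ry
        qz = corners[k, e2, 2] - rz
        s1 = px * shat[k, e, 0] + py * shat[k, e, 1] + pz * shat[k, e, 2]
        s2 = qx * shat[k, e, 0] + qy * shat[k, e, 1] + qz * shat[k, e, 2]
        R1 = math.sqrt(px * px + py * py + pz * pz + h * h)
        R2 = math.sqrt(qx * qx + qy * qy + qz * qz + h * h)
        f2 = _edge_f2(R1, s1, R2, s2)
        i3x -= mhat[k, e, 0] * f2
        i3y -= mhat[k, e, 1] * f2
        i3z -= mhat[k, e, 2] * f2
    om = _vos_solid_angle(
        corners[k, 0, 0] - xx, corners[k, 0, 1] - xy, corners[k, 0, 2] - xz,
        corners[k, 1, 0] - xx, corners[k, 1, 1] - xy, corners[k, 1, 2] - xz,
        corners[k, 2, 0] - xx, corners[k, 2, 1] - xy, corners[k, 2, 2] - xz)
    out0 = 0.0
    out1 = 0.0
    out2 = 0.0
    # phi_j(rho) by affine extension: phi_j(rho) = delta_j0 + g_j.(rho - p0)
    ex = rx - corners[k, 0, 0]
    ey = ry - corners[k, 0, 1]
    ez = rz - corners[k, 0, 2]
    for j in range(3):
        gx, gy, gz = grads[k, j, 0], grads[k, j, 1], grads[k, j, 2]
        phi = (1.0 if j == 0 else 0.0) + gx * ex + gy * ey + gz * ez
        out = -om * phi + h * (gx * i3x + gy * i3y + gz * i3z)
        if j == 0:
            out0 = out
        elif j == 1:
            out1 = out
        else:
            out2 = out
    return out0, out1, out2


# ---------------------------------------------------------------------------
# Galerkin double integrals with adaptive outer subdivision
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _gauss_S_on_tri(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                    qb, qw, corners, shat, mhat, nhat, l):
    """One quadrature pass of int_{T_outer} K1(x; T_l) dS(x)."""
    ux, uy, uz = a1x - a0x, a1y - a0y, a1z - a0z
    vx, vy, vz = a2x - a0x, a2y - a0y, a2z - a0z
    wx_ = uy * vz - uz * vy
    wy_ = uz * vx - ux * vz
    wz_ = ux * vy - uy * vx
    area = 0.5 * math.sqrt(wx_ * wx_ + wy_ * wy_ + wz_ * wz_)
    acc = 0.0
    for q in range(qb.shape[0]):
        b0, b1, b2 = qb[q, 0], qb[q, 1], qb[q, 2]
        xx = b0 * a0x + b1 * a1x + b2 * a2x
        xy = b0 * a0y + b1 * a1y + b2 * a2y
        xz = b0 * a0z + b1 * a1z + b2 * a2z
        acc += qw[q] * _analytic_S(xx, xy, xz, corners, shat, mhat, nhat, l)
    return acc * area


@njit(cache=True, fastmath=True)
def _adaptive_S_pair(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                     qb, qw, corners, shat, mhat, nhat, l,
                     tol, maxdepth):
    """Adaptive recursive outer subdivision for one triangle pair."""
    # stack entries: 9 corner coords, depth, coarse estimate
    stack = np.empty((4 * maxdepth + 8, 11))
    coarse = _gauss_S_on_tri(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                             qb, qw, corners, shat, mhat, nhat, l)
    stack[0, 0] = a0x
    stack[0, 1] = a0y
    stack[0, 2] = a0z
    stack[0, 3] = a1x
    stack[0, 4] = a1y
    stack[0, 5] = a1z
    stack[0, 6] = a2x
    stack[0, 7] = a2y
    stack[0, 8] = a2z
    stack[0, 9] = 0.0
    stack[0, 10] = coarse
    sp = 1
    total = 0.0
    while sp > 0:
        sp -= 1
        c0x, c0y, c0z = stack[sp, 0], stack[sp, 1], stack[sp, 2]
        c1x, c1y, c1z = stack[sp, 3], stack[sp, 4], stack[sp, 5]
        c2x, c2y, c2z = stack[sp, 6], stack[sp, 7], stack[sp, 8]
        depth = stack[sp, 9]
        coarse = stack[sp, 10]
        m01x, m01y, m01z = 0.5 * (c0x + c1x), 0.5 * (c0y + c1y), 0.5 * (c0z + c1z)
        m12x, m12y, m12z = 0.5 * (c1x + c2x), 0.5 * (c1y + c2y), 0.5 * (c1z + c2z)
        m20x, m20y, m20z = 0.5 * (c2x + c0x), 0.5 * (c2y + c0y), 0.5 * (c2z + c0z)
        f0 = _gauss_S_on_tri(c0x, c0y, c0z, m01x, m01y, m01z, m20x, m20y, m20z,
                             qb, qw, corners, shat, mhat, nhat, l)
        f1 = _gauss_S_on_tri(c1x, c1y, c1z, m12x, m12y, m12z, m01x, m01y, m01z,
                             qb, qw, corners, shat, mhat, nhat, l)
        f2_ = _gauss_S_on_tri(c2x, c2y, c2z, m20x, m20y, m20z, m12x, m12y, m12z,
                              qb, qw, corners, shat, mhat, nhat, l)
        f3 = _gauss_S_on_tri(m01x, m01y, m01z, m12x, m12y, m12z, m20x, m20y, m20z,
                             qb, qw, corners, shat, mhat, nhat, l)
        fine = f0 + f1 + f2_ + f3
        if abs(fine - coarse) <= tol * abs(fine) + 1e-300 or depth >= maxdepth:
            total += fine
        else:
            stack[sp, 0] = c0x
            stack[sp, 1] = c0y
            stack[sp, 2] = c0z
            stack[sp, 3] = m01x
            stack[sp, 4] = m01y
            stack[sp, 5] = m01z
            stack[sp, 6] = m20x
            stack[sp, 7] = m20y
            stack[sp, 8] = m20z
            stack[sp, 9] = depth + 1
            stack[sp, 10] = f0
            stack[sp + 1, 0] = c1x
            stack[sp + 1, 1] = c1y
            stack[sp + 1, 2] = c1z
            stack[sp + 1, 3] = m12x
            stack[sp + 1, 4] = m12y
            stack[sp + 1, 5] = m12z
            stack[sp + 1, 6] = m01x
            stack[sp + 1, 7] = m01y
            stack[sp + 1, 8] = m01z
            stack[sp + 1, 9] = depth + 1
            stack[sp + 1, 10] = f1
            stack[sp + 2, 0] = c2x
            stack[sp + 2, 1] = c2y
            stack[sp + 2, 2] = c2z
            stack[sp + 2, 3] = m20x
            stack[sp + 2, 4] = m20y
            stack[sp + 2, 5] = m20z
            stack[sp + 2, 6] = m12x
            stack[sp + 2, 7] = m12y
            stack[sp + 2, 8] = m12z
            stack[sp + 2, 9] = depth + 1
            stack[sp + 2, 10] = f2_
            stack[sp + 3, 0] = m01x
            stack[sp + 3, 1] = m01y
            stack[sp + 3, 2] = m01z
            stack[sp + 3, 3] = m12x
            stack[sp + 3, 4] = m12y
            stack[sp + 3, 5] = m12z
            stack[sp + 3, 6] = m20x
            stack[sp + 3, 7] = m20y
            stack[sp + 3, 8] = m20z
            stack[sp + 3, 9] = depth + 1
            stack[sp + 3, 10] = f3
            sp += 4
    return total


@njit(cache=True, fastmath=True)
def galerkin_ss(cenA, scaleA, cornA, cenB, scaleB, cornB,
                shatB, mhatB, nhatB,
                qb, qw, adaptive, tol, maxdepth, far_factor, same_mesh,
                mode=0):
    """(nTA, nTB) matrix of raw double integrals int_{T_k} int_{T_l} 1/R.

    Far pairs get one base-rule pass; near pairs are refined adaptively when
    ``adaptive`` is set.  ``same_mesh`` exploits/enforces exact symmetry.
    ``mode`` restricts the computed pairs: 0 = all, 1 = far pairs only,
    2 = near pairs only (zeros elsewhere), so that assemblies differing only
    in their near-pair treatment can share the far-pair work.
    """
    nta = cornA.shape[0]
    ntb = cornB.shape[0]
    out = np.zeros((nta, ntb))
    for k in range(nta):
        a0x, a0y, a0z = cornA[k, 0, 0], cornA[k, 0, 1], cornA[k, 0, 2]
        a1x, a1y, a1z = cornA[k, 1, 0], cornA[k, 1, 1], cornA[k, 1, 2]
        a2x, a2y, a2z = cornA[k, 2, 0], cornA[k, 2, 1], cornA[k, 2, 2]
        lstart = k if same_mesh else 0
        for l in range(lstart, ntb):
            dx = cenA[k, 0] - cenB[l, 0]
            dy = cenA[k, 1] - cenB[l, 1]
            dz = cenA[k, 2] - cenB[l, 2]
            dist = math.sqrt(dx * dx + dy * dy + dz * dz)
            near = dist < far_factor * (scaleA[k] + scaleB[l])
            if (mode == 1 and near) or (mode == 2 and not near):
                continue
            if adaptive and near:
                val = _adaptive_S_pair(a0x, a0y, a0z, a1x, a1y, a1z,
                                       a2x, a2y, a2z, qb, qw,
                                       cornB, shatB, mhatB, nhatB, l,
                                       tol, maxdepth)
            else:
                val = _gauss_S_on_tri(a0x, a0y, a0z, a1x, a1y, a1z,
                                      a2x, a2y, a2z, qb, qw,
                                      cornB, shatB, mhatB, nhatB, l)
            out[k, l] = val
            if same_mesh and l != k:
                out[l, k] = val
    return out


@njit(cache=True, inline="always", fastmath=True)
def _gauss_D_on_tri(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                    qb, qw, corners, shat, mhat, nhat, grads, scale, l):
    ux, uy, uz = a1x - a0x, a1y - a0y, a1z - a0z
    vx, vy, vz = a2x - a0x, a2y - a0y, a2z - a0z
    wx_ = uy * vz - uz * vy
    wy_ = uz * vx - ux * vz
    wz_ = ux * vy - uy * vx
    area = 0.5 * math.sqrt(wx_ * wx_ + wy_ * wy_ + wz_ * wz_)
    acc0 = 0.0
    acc1 = 0.0
    acc2 = 0.0
    for q in range(qb.shape[0]):
        b0, b1, b2 = qb[q, 0], qb[q, 1], qb[q, 2]
        xx = b0 * a0x + b1 * a1x + b2 * a2x
        xy = b0 * a0y + b1 * a1y + b2 * a2y
        xz = b0 * a0z + b1 * a1z + b2 * a2z
        d0, d1, d2 = _analytic_D(xx, xy, xz, corners, shat, mhat, nhat,
                                 grads, scale, l)
        acc0 += qw[q] * d0
        acc1 += qw[q] * d1
        acc2 += qw[q] * d2
    return acc0 * area, acc1 * area, acc2 * area


@njit(cache=True, fastmath=True)
def _adaptive_D_pair(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                     qb, qw, corners, shat, mhat, nhat, grads, scale, l,
                     tol, maxdepth):
    stack = np.empty((4 * maxdepth + 8, 13))
    c0, c1, c2 = _gauss_D_on_tri(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                                 qb, qw, corners, shat, mhat, nhat, grads,
                                 scale, l)
    stack[0, 0] = a0x
    stack[0, 1] = a0y
    stack[0, 2] = a0z
    stack[0, 3] = a1x
    stack[0, 4] = a1y
    stack[0, 5] = a1z
    stack[0, 6] = a2x
    stack[0, 7] = a2y
    stack[0, 8] = a2z
    stack[0, 9] = 0.0
    stack[0, 10] = c0
    stack[0, 11] = c1
    stack[0, 12] = c2
    sp = 1
    t0 = 0.0
    t1 = 0.0
    t2 = 0.0
    while sp > 0:
        sp -= 1
        b0x, b0y, b0z = stack[sp, 0], stack[sp, 1], stack[sp, 2]
        b1x, b1y, b1z = stack[sp, 3], stack[sp, 4], stack[sp, 5]
        b2x, b2y, b2z = stack[sp, 6], stack[sp, 7], stack[sp, 8]
        depth = stack[sp, 9]
        co0, co1, co2 = stack[sp, 10], stack[sp, 11], stack[sp, 12]
        m01x, m01y, m01z = 0.5 * (b0x + b1x), 0.5 * (b0y + b1y), 0.5 * (b0z + b1z)
        m12x, m12y, m12z = 0.5 * (b1x + b2x), 0.5 * (b1y + b2y), 0.5 * (b1z + b2z)
        m20x, m20y, m20z = 0.5 * (b2x + b0x), 0.5 * (b2y + b0y), 0.5 * (b2z + b0z)
        f00, f01, f02 = _gauss_D_on_tri(b0x, b0y, b0z, m01x, m01y, m01z,
                                        m20x, m20y, m20z, qb, qw, corners,
                                        shat, mhat, nhat, grads, scale, l)
        f10, f11, f12 = _gauss_D_on_tri(b1x, b1y, b1z, m12x, m12y, m12z,
                                        m01x, m01y, m01z, qb, qw, corners,
                                        shat, mhat, nhat, grads, scale, l)
        f20, f21, f22 = _gauss_D_on_tri(b2x, b2y, b2z, m20x, m20y, m20z,
                                        m12x, m12y, m12z, qb, qw, corners,
                                        shat, mhat, nhat, grads, scale, l)
        f30, f31, f32 = _gauss_D_on_tri(m01x, m01y, m01z, m12x, m12y, m12z,
                                        m20x, m20y, m20z, qb, qw, corners,
                                        shat, mhat, nhat, grads, scale, l)
        fi0 = f00 + f10 + f20 + f30
        fi1 = f01 + f11 + f21 + f31
        fi2 = f02 + f12 + f22 + f32
        ref = abs(fi0) + abs(fi1) + abs(fi2)
        err = abs(fi0 - co0) + abs(fi1 - co1) + abs(fi2 - co2)
        if err <= tol * ref + 1e-300 or depth >= maxdepth:
            t0 += fi0
            t1 += fi1
            t2 += fi2
        else:
            stack[sp, 0] = b0x
            stack[sp, 1] = b0y
            stack[sp, 2] = b0z
            stack[sp, 3] = m01x
            stack[sp, 4] = m01y
            stack[sp, 5] = m01z
            stack[sp, 6] = m20x
            stack[sp, 7] = m20y
            stack[sp, 8] = m20z
            stack[sp, 9] = depth + 1
            stack[sp, 10] = f00
            stack[sp, 11] = f01
            stack[sp, 12] = f02
            stack[sp + 1, 0] = b1x
            stack[sp + 1, 1] = b1y
            stack[sp + 1, 2] = b1z
            stack[sp + 1, 3] = m12x
            stack[sp + 1, 4] = m12y
            stack[sp + 1, 5] = m12z
            stack[sp + 1, 6] = m01x
            stack[sp + 1, 7] = m01y
            stack[sp + 1, 8] = m01z
            stack[sp + 1, 9] = depth + 1
            stack[sp + 1, 10] = f10
            stack[sp + 1, 11] = f11
            stack[sp + 1, 12] = f12
            stack[sp + 2, 0] = b2x
            stack[sp + 2, 1] = b2y
            stack[sp + 2, 2] = b2z
            stack[sp + 2, 3] = m20x
            stack[sp + 2, 4] = m20y
            stack[sp + 2, 5] = m20z
            stack[sp + 2, 6] = m12x
            stack[sp + 2, 7] = m12y
            stack[sp + 2, 8] = m12z
            stack[sp + 2, 9] = depth + 1
            stack[sp + 2, 10] = f20
            stack[sp + 2, 11] = f21
            stack[sp + 2, 12] = f22
            stack[sp + 3, 0] = m01x
            stack[sp + 3, 1] = m01y
            stack[sp + 3, 2] = m01z
            stack[sp + 3, 3] = m12x
            stack[sp + 3, 4] = m12y
            stack[sp + 3, 5] = m12z
            stack[sp + 3, 6] = m20x
            stack[sp + 3, 7] = m20y
            stack[sp + 3, 8] = m20z
            stack[sp + 3, 9] = depth + 1
            stack[sp + 3, 10] = f30
            stack[sp + 3, 11] = f31
            stack[sp + 3, 12] = f32
            sp += 4
    return t0, t1, t2


@njit(cache=True, fastmath=True)
def galerkin_d(cenA, scaleA, cornA, cenB, scaleB, cornB,
               shatB, mhatB, nhatB, gradsB, trisB, nvb,
               qb, qw, adaptive, tol, maxdepth, far_factor, same_mesh,
               mode=0):
    """(nTA, nVB) matrix of raw int_{T_k} int_{S_B} dG/dn' phi_j (times 4pi).

    ``same_mesh`` skips the k == l pair (principal value: coplanar
    contributions vanish; truly coplanar off-pairs are zeroed analytically).
    """
    nta = cornA.shape[0]
    ntb = cornB.shape[0]
    out = np.zeros((nta, nvb))
    for k in range(nta):
        a0x, a0y, a0z = cornA[k, 0, 0], cornA[k, 0, 1], cornA[k, 0, 2]
        a1x, a1y, a1z = cornA[k, 1, 0], cornA[k, 1, 1], cornA[k, 1, 2]
        a2x, a2y, a2z = cornA[k, 2, 0], cornA[k, 2, 1], cornA[k, 2, 2]
        for l in range(ntb):
            if same_mesh and l == k:
                continue
            dx = cenA[k, 0] - cenB[l, 0]
            dy = cenA[k, 1] - cenB[l, 1]
            dz = cenA[k, 2] - cenB[l, 2]
            dist = math.sqrt(dx * dx + dy * dy + dz * dz)
            near = dist < far_factor * (scaleA[k] + scaleB[l])
            if (mode == 1 and near) or (mode == 2 and not near):
                continue
            if adaptive and near:
                v0, v1, v2 = _adaptive_D_pair(
                    a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z, qb, qw,
                    cornB, shatB, mhatB, nhatB, gradsB, scaleB, l,
                    tol, maxdepth)
            else:
                v0, v1, v2 = _gauss_D_on_tri(
                    a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z, qb, qw,
                    cornB, shatB, mhatB, nhatB, gradsB, scaleB, l)
            out[k, trisB[l, 0]] += v0
            out[k, trisB[l, 1]] += v1
            out[k, trisB[l, 2]] += v2
    return out


# ---------------------------------------------------------------------------
# pointwise evaluations (internal potential rows, analytic integrals API)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def point_sd(points, cornB, shatB, mhatB, nhatB, gradsB, scaleB, trisB, nvb):
    """Per-point analytic single/double layer rows.

    Returns (S (np, nTB) raw int_T 1/R, D (np, nVB) raw assembled
    int_T dG/dn' phi_j * 4pi).
    """
    npts = points.shape[0]
    ntb = cornB.shape[0]
    s_out = np.zeros((npts, ntb))
    d_out = np.zeros((npts, nvb))
    for i in range(npts):
        xx, xy, xz = points[i, 0], points[i, 1], points[i, 2]
        for l in range(ntb):
            s_out[i, l] = _analytic_S(xx, xy, xz, cornB, shatB, mhatB,
                                      nhatB, l)
            d0, d1, d2 = _analytic_D(xx, xy, xz, cornB, shatB, mhatB, nhatB,
                                     gradsB, scaleB, l)
            d_out[i, trisB[l, 0]] += d0
            d_out[i, trisB[l, 1]] += d1
            d_out[i, trisB[l, 2]] += d2
    return s_out, d_out


# ---------------------------------------------------------------------------
# dipole right-hand sides
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def dipole_p0_integrals(r0, q, cornB, shatB, mhatB, nhatB, scaleB):
    """Exact int_T q.(r'-r0)/||r'-r0||^3 dS' per triangle (times 4pi missing:
    raw values; equals Iv3 + Omega_signed * nhat contracted with q)."""
    ntb = cornB.shape[0]
    out = np.zeros(ntb)
    xx, xy, xz = r0[0], r0[1], r0[2]
    qx, qy, qz = q[0], q[1], q[2]
    for l in range(ntb):
        nx, ny, nz = nhatB[l, 0], nhatB[l, 1], nhatB[l, 2]
        dx = xx - cornB[l, 0, 0]
        dy = xy - cornB[l, 0, 1]
        dz = xz - cornB[l, 0, 2]
        h = dx * nx + dy * ny + dz * nz
        rx, ry, rz = xx - h * nx, xy - h * ny, xz - h * nz
        i3x = 0.0
        i3y = 0.0
        i3z = 0.0
        for e in range(3):
            e2 = (e + 1) % 3
            px = cornB[l, e, 0] - rx
            py = cornB[l, e, 1] - ry
            pz = cornB[l, e, 2] - rz
            ax = cornB[l, e2, 0] - rx
            ay = cornB[l, e2, 1] - ry
            az = cornB[l, e2, 2] - rz
            s1 = px * shatB[l, e, 0] + py * shatB[l, e, 1] + pz * shatB[l, e, 2]
            s2 = ax * shatB[l, e, 0] + ay * shatB[l, e, 1] + az * shatB[l, e, 2]
            R1 = math.sqrt(px * px + py * py + pz * pz + h * h)
            R2 = math.sqrt(ax * ax + ay * ay + az * az + h * h)
            f2 = _edge_f2(R1, s1, R2, s2)
            i3x -= mhatB[l, e, 0] * f2
            i3y -= mhatB[l, e, 1] * f2
            i3z -= mhatB[l, e, 2] * f2
        om = _vos_solid_angle(
            cornB[l, 0, 0] - xx, cornB[l, 0, 1] - xy, cornB[l, 0, 2] - xz,
            cornB[l, 1, 0] - xx, cornB[l, 1, 1] - xy, cornB[l, 1, 2] - xz,
            cornB[l, 2, 0] - xx, cornB[l, 2, 1] - xy, cornB[l, 2, 2] - xz)
        out[l] = (qx * (i3x + om * nx) + qy * (i3y + om * ny)
                  + qz * (i3z + om * nz))
    return out


@njit(cache=True, inline="always", fastmath=True)
def _dip_der_gauss(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                   r0x, r0y, r0z, qx, qy, qz, nx, ny, nz,
                   g, p00, p01, p02, qb, qw):
    """One pass of int_T phi_j(r') n.grad v(r') dS' (times 4pi) for the three
    P1 functions; g are the in-plane gradients, p0* a corner of the support
    triangle of the P1 pack (affine extension is exact)."""
    ux, uy, uz = a1x - a0x, a1y - a0y, a1z - a0z
    vx, vy, vz = a2x - a0x, a2y - a0y, a2z - a0z
    wx_ = uy * vz - uz * vy
    wy_ = uz * vx - ux * vz
    wz_ = ux * vy - uy * vx
    area = 0.5 * math.sqrt(wx_ * wx_ + wy_ * wy_ + wz_ * wz_)
    acc0 = 0.0
    acc1 = 0.0
    acc2 = 0.0
    for iq in range(qb.shape[0]):
        b0, b1, b2 = qb[iq, 0], qb[iq, 1], qb[iq, 2]
        xx = b0 * a0x + b1 * a1x + b2 * a2x
        xy = b0 * a0y + b1 * a1y + b2 * a2y
        xz = b0 * a0z + b1 * a1z + b2 * a2z
        dx, dy, dz = xx - r0x, xy - r0y, xz - r0z
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        r3 = r2 * r
        r5 = r3 * r2
        qdotd = qx * dx + qy * dy + qz * dz
        ndotd = nx * dx + ny * dy + nz * dz
        qdotn = qx * nx + qy * ny + qz * nz
        val = qdotn / r3 - 3.0 * qdotd * ndotd / r5
        ex, ey, ez = xx - p00, xy - p01, xz - p02
        w = qw[iq] * val
        phi0 = 1.0 + g[0, 0] * ex + g[0, 1] * ey + g[0, 2] * ez
        phi1 = g[1, 0] * ex + g[1, 1] * ey + g[1, 2] * ez
        phi2 = g[2, 0] * ex + g[2, 1] * ey + g[2, 2] * ez
        acc0 += w * phi0
        acc1 += w * phi1
        acc2 += w * phi2
    return acc0 * area, acc1 * area, acc2 * area


@njit(cache=True, fastmath=True)
def dipole_p1_integrals(r0, q, cornB, nhatB, gradsB, trisB, nvb,
                        qb, qw, adaptive, tol, maxdepth):
    """Galerkin <phi_a, dv/dn> over a surface for the infinite-medium dipole
    potential v (raw: times 4pi), with adaptive subdivision near the dipole."""
    ntb = cornB.shape[0]
    out = np.zeros(nvb)
    r0x, r0y, r0z = r0[0], r0[1], r0[2]
    qx, qy, qz = q[0], q[1], q[2]
    for l in range(ntb):
        a0x, a0y, a0z = cornB[l, 0, 0], cornB[l, 0, 1], cornB[l, 0, 2]
        a1x, a1y, a1z = cornB[l, 1, 0], cornB[l, 1, 1], cornB[l, 1, 2]
        a2x, a2y, a2z = cornB[l, 2, 0], cornB[l, 2, 1], cornB[l, 2, 2]
        nx, ny, nz = nhatB[l, 0], nhatB[l, 1], nhatB[l, 2]
        g = gradsB[l]
        if not adaptive:
            v0, v1, v2 = _dip_der_gauss(a0x, a0y, a0z, a1x, a1y, a1z,
                                        a2x, a2y, a2z, r0x, r0y, r0z,
                                        qx, qy, qz, nx, ny, nz, g,
                                        a0x, a0y, a0z, qb, qw)
        else:
            v0, v1, v2 = _adaptive_dip_pair(a0x, a0y, a0z, a1x, a1y, a1z,
                                            a2x, a2y, a2z, r0x, r0y, r0z,
                                            qx, qy, qz, nx, ny, nz, g,
                                            qb, qw, tol, maxdepth)
        out[trisB[l, 0]] += v0
        out[trisB[l, 1]] += v1
        out[trisB[l, 2]] += v2
    return out


@njit(cache=True, fastmath=True)
def _adaptive_dip_pair(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                       r0x, r0y, r0z, qx, qy, qz, nx, ny, nz, g,
                       qb, qw, tol, maxdepth):
    stack = np.empty((4 * maxdepth + 8, 13))
    c0, c1, c2 = _dip_der_gauss(a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                                r0x, r0y, r0z, qx, qy, qz, nx, ny, nz, g,
                                a0x, a0y, a0z, qb, qw)
    stack[0, 0] = a0x
    stack[0, 1] = a0y
    stack[0, 2] = a0z
    stack[0, 3] = a1x
    stack[0, 4] = a1y
    stack[0, 5] = a1z
    stack[0, 6] = a2x
    stack[0, 7] = a2y
    stack[0, 8] = a2z
    stack[0, 9] = 0.0
    stack[0, 10] = c0
    stack[0, 11] = c1
    stack[0, 12] = c2
    sp = 1
    t0 = 0.0
    t1 = 0.0
    t2 = 0.0
    while sp > 0:
        sp -= 1
        b0x, b0y, b0z = stack[sp, 0], stack[sp, 1], stack[sp, 2]
        b1x, b1y, b1z = stack[sp, 3], stack[sp, 4], stack[sp, 5]
        b2x, b2y, b2z = stack[sp, 6], stack[sp, 7], stack[sp, 8]
        depth = stack[sp, 9]
        co0, co1, co2 = stack[sp, 10], stack[sp, 11], stack[sp, 12]
        m01x, m01y, m01z = 0.5 * (b0x + b1x), 0.5 * (b0y + b1y), 0.5 * (b0z + b1z)
        m12x, m12y, m12z = 0.5 * (b1x + b2x), 0.5 * (b1y + b2y), 0.5 * (b1z + b2z)
        m20x, m20y, m20z = 0.5 * (b2x + b0x), 0.5 * (b2y + b0y), 0.5 * (b2z + b0z)
        f00, f01, f02 = _dip_der_gauss(b0x, b0y, b0z, m01x, m01y, m01z,
                                       m20x, m20y, m20z, r0x, r0y, r0z,
                                       qx, qy, qz, nx, ny, nz, g,
                                       a0x, a0y, a0z, qb, qw)
        f10, f11, f12 = _dip_der_gauss(b1x, b1y, b1z, m12x, m12y, m12z,
                                       m01x, m01y, m01z, r0x, r0y, r0z,
                                       qx, qy, qz, nx, ny, nz, g,
                                       a0x, a0y, a0z, qb, qw)
        f20, f21, f22 = _dip_der_gauss(b2x, b2y, b2z, m20x, m20y, m20z,
                                       m12x, m12y, m12z, r0x, r0y, r0z,
                                       qx, qy, qz, nx, ny, nz, g,
                                       a0x, a0y, a0z, qb, qw)
        f30, f31, f32 = _dip_der_gauss(m01x, m01y, m01z, m12x, m12y, m12z,
                                       m20x, m20y, m20z, r0x, r0y, r0z,
                                       qx, qy, qz, nx, ny, nz, g,
                                       a0x, a0y, a0z, qb, qw)
        fi0 = f00 + f10 + f20 + f30
        fi1 = f01 + f11 + f21 + f31
        fi2 = f02 + f12 + f22 + f32
        ref = abs(fi0) + abs(fi1) + abs(fi2)
        err = abs(fi0 - co0) + abs(fi1 - co1) + abs(fi2 - co2)
        if err <= tol * ref + 1e-300 or depth >= maxdepth:
            t0 += fi0
            t1 += fi1
            t2 += fi2
        else:
            stack[sp, 0] = b0x
            stack[sp, 1] = b0y
            stack[sp, 2] = b0z
            stack[sp, 3] = m01x
            stack[sp, 4] = m01y
            stack[sp, 5] = m01z
            stack[sp, 6] = m20x
            stack[sp, 7] = m20y
            stack[sp, 8] = m20z
            stack[sp, 9] = depth + 1
            stack[sp, 10] = f00
            stack[sp, 11] = f01
            stack[sp, 12] = f02
            stack[sp + 1, 0] = b1x
            stack[sp + 1, 1] = b1y
            stack[sp + 1, 2] = b1z
            stack[sp + 1, 3] = m12x
            stack[sp + 1, 4] = m12y
            stack[sp + 1, 5] = m12z
            stack[sp + 1, 6] = m01x
            stack[sp + 1, 7] = m01y
            stack[sp + 1, 8] = m01z
            stack[sp + 1, 9] = depth + 1
            stack[sp + 1, 10] = f10
            stack[sp + 1, 11] = f11
            stack[sp + 1, 12] = f12
            stack[sp + 2, 0] = b2x
            stack[sp + 2, 1] = b2y
            stack[sp + 2, 2] = b2z
            stack[sp + 2, 3] = m20x
            stack[sp + 2, 4] = m20y
            stack[sp + 2, 5] = m20z
            stack[sp + 2, 6] = m12x
            stack[sp + 2, 7] = m12y
            stack[sp + 2, 8] = m12z
            stack[sp + 2, 9] = depth + 1
            stack[sp + 2, 10] = f20
            stack[sp + 2, 11] = f21
            stack[sp + 2, 12] = f22
            stack[sp + 3, 0] = m01x
            stack[sp + 3, 1] = m01y
            stack[sp + 3, 2] = m01z
            stack[sp + 3, 3] = m12x
            stack[sp + 3, 4] = m12y
            stack[sp + 3, 5] = m12z
            stack[sp + 3, 6] = m20x
            stack[sp + 3, 7] = m20y
            stack[sp + 3, 8] = m20z
            stack[sp + 3, 9] = depth + 1
            stack[sp + 3, 10] = f30
            stack[sp + 3, 11] = f31
            stack[sp + 3, 12] = f32
            sp += 4
    return t0, t1, t2
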
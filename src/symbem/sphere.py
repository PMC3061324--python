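"""Closed-form and series solutions on concentric spheres.

These are independent reference solutions used to validate the numerical
solver: the Legendre-series potential of a dipole in a multilayer sphere
(surface, interior and exterior-layer evaluation), the closed-form magnetic
field of a dipole in a spherically symmetric conductor, and the Neumann
series for boundary current injection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, lpmv  # noqa: used by the dipole series

__all__ = [
    "SphereModel",
    "eeg_sphere_potential",
    "ip_sphere_potential",
    "meg_sphere_field",
    "eit_sphere_potential",
]

MU0 = 4.0e-7 * np.pi


@dataclass(frozen=True)
class SphereModel:
    """Concentric sphere model: increasing radii (m), conductivities (S/m),
    series truncation order L."""

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]
    L: int = 100

    def __post_init__(self):
        r = tuple(float(x) for x in self.radii)
        s = tuple(float(x) for x in self.conductivities)
        if len(r) != len(s):
            raise ValueError("radii/conductivities length mismatch")
        if any(b <= a for a, b in zip(r, r[1:])) or r[0] <= 0:
            raise ValueError("radii must be strictly increasing and positive")
        if any(x <= 0 for x in s):
            raise ValueError("conductivities must be positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "conductivities", s)

    @property
    def n_layers(self) -> int:
        return len(self.radii)


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R v parallel to +z (identity for v = 0)."""
    n = np.linalg.norm(v)
    if n == 0:
        return np.eye(3)
    a = v / n
    z = np.array([0.0, 0.0, 1.0])
    c = float(a @ z)
    if c > 1 - 1e-14:
        return np.eye(3)
    if c < -1 + 1e-14:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(a, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _layer_radial_solution(model: SphereModel, l: int):
    """Per-layer coefficients of the l-th harmonic for a unit source term.

    The potential in layer i is written, for evaluation radius r,

        f_i(r) = A_i (r / rho_N)^l + B_i (rho_1 / r)^(l+1)

    and the dipole source in layer 1 contributes (rho_1/r)^(l+1) with a
    known coefficient beta (scaled by the caller).  Returns the (A_i, B_i)
    with B_1 the coefficient multiplying the unit source strength, i.e.
    solves the transmission + outer Neumann problem with beta = 1.
    """
    rho = np.array(model.radii)
    sig = np.array(model.conductivities)
    N = model.n_layers
    rN, r1 = rho[-1], rho[0]
    # unknowns: A_1, (A_i, B_i) for i = 2..N  -> 2N-1
    nun = 2 * N - 1
    M = np.zeros((nun, nun))
    rhs = np.zeros(nun)

    def idx_A(i):  # 1-based layer
        return 0 if i == 1 else 2 * i - 3

    def idx_B(i):
        return 2 * i - 2

    def u(r):  # regular solution and its derivative
        return (r / rN) ** l, l * (r / rN) ** l / r

    def w(r):  # decaying solution and its derivative
        return (r1 / r) ** (l + 1), -(l + 1) * (r1 / r) ** (l + 1) / r

    row = 0
    for i in range(1, N):  # interface at rho_i between layers i, i+1
        r = rho[i - 1]
        uv, ud = u(r)
        wv, wd = w(r)
        # continuity of f
        M[row, idx_A(i)] += uv
        if i > 1:
            M[row, idx_B(i)] += wv
        else:
            rhs[row] -= wv  # beta = 1 source in layer 1
        M[row, idx_A(i + 1)] -= uv
        M[row, idx_B(i + 1)] -= wv
        row += 1
        # continuity of sigma f'
        M[row, idx_A(i)] += sig[i - 1] * ud
        if i > 1:
            M[row, idx_B(i)] += sig[i - 1] * wd
        else:
            rhs[row] -= sig[i - 1] * wd
        M[row, idx_A(i + 1)] -= sig[i] * ud
        M[row, idx_B(i + 1)] -= sig[i] * wd
        row += 1
    # outer boundary: sigma_N f'(rho_N) = 0
    uv, ud = u(rN)
    wv, wd = w(rN)
    M[row, idx_A(N)] += ud
    if N > 1:
        M[row, idx_B(N)] += wd
    else:
        rhs[row] -= wd
    sol = np.linalg.solve(M, rhs)
    A = np.zeros(N + 1)
    B = np.zeros(N + 1)
    A[1] = sol[0]
    B[1] = 1.0
    for i in range(2, N + 1):
        A[i] = sol[idx_A(i)]
        B[i] = sol[idx_B(i)]
    return A, B


def _dipole_source_coefficients(model: SphereModel, z0: float, q_rot,
                                L: int):
    """Source expansion coefficients beta_l such that the infinite-medium
    potential of the dipole (on the +z axis at z0, moment q_rot) reads, for
    r > z0,

        v(r) = sum_l (rho_1/r)^(l+1) [ bz_l P_l(cos t) +
                                       bt_l P_l^1(cos t) (qx cos p + qy sin p)/qt ]

    Returns (bz, bt) arrays of shape (L+1,); the angular factors are applied
    by the caller.
    """
    sigma1 = model.conductivities[0]
    r1 = model.radii[0]
    ls = np.arange(L + 1, dtype=float)
    # (z0)^(l-1) / rho_1^(l+1), stable for z0 < rho_1
    with np.errstate(divide="ignore"):
        ratio = np.where(ls >= 1, (z0 / r1) ** np.maximum(ls - 1, 0), 0.0)
    base = ratio / r1 ** 2
    base[0] = 0.0
    if z0 == 0.0:
        base = np.zeros(L + 1)
        base[1] = 1.0 / r1 ** 2
    bz = base * ls * q_rot[2] / (4 * np.pi * sigma1)
    # scipy's lpmv carries the Condon-Shortley phase: P_1^1 = -sin(theta),
    # hence the minus sign on the tangential coefficient
    bt = -base / (4 * np.pi * sigma1)
    return bz, bt


def _evaluate_series(model: SphereModel, dipole_pos, dipole_mom, points,
                     L: int):
    """Potential of a dipole (innermost layer) at arbitrary points inside
    the model.  Points in layer 1 use the exact infinite-medium term plus
    the regular series correction; points in outer layers use the full
    series."""
    rho = np.array(model.radii)
    sig = np.array(model.conductivities)
    N = model.n_layers
    r0 = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(dipole_mom, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    z0 = float(np.linalg.norm(r0))
    if z0 >= rho[0]:
        raise ValueError("dipole must lie strictly inside the innermost "
                         "sphere")
    R = _rotation_to_z(r0)
    q_rot = R @ q
    pts = points @ R.T
    r = np.linalg.norm(pts, axis=1)
    if (r > rho[-1] * (1 + 1e-9)).any():
        raise ValueError("evaluation points must lie inside the model")
    cos_t = np.divide(pts[:, 2], r, out=np.zeros_like(r), where=r > 0)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    rxy = np.hypot(pts[:, 0], pts[:, 1])
    cos_p = np.divide(pts[:, 0], rxy, out=np.ones_like(rxy), where=rxy > 0)
    sin_p = np.divide(pts[:, 1], rxy, out=np.zeros_like(rxy), where=rxy > 0)

    bz, bt = _dipole_source_coefficients(model, z0, q_rot, L)
    ls = np.arange(L + 1)
    # per-point layer index (1-based); points numerically on an interface
    # are attached to the outer layer
    layer = np.searchsorted(rho * (1 + 1e-9), r) + 1
    layer = np.minimum(layer, N)

    rN, r1 = rho[-1], rho[0]
    # radial factors per l per point
    A = np.zeros((N + 1, L + 1))
    B = np.zeros((N + 1, L + 1))
    for l in range(1, L + 1):
        Al, Bl = _layer_radial_solution(model, l)
        A[:, l] = Al
        B[:, l] = Bl

    # Legendre functions
    P = np.stack([eval_legendre(l, cos_t) for l in ls], axis=1)
    P1 = np.stack([lpmv(1, l, cos_t) for l in ls], axis=1)
    tang = q_rot[0] * cos_p + q_rot[1] * sin_p

    npts = len(pts)
    lsf = ls.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        uu = np.power.outer(r / rN, lsf)                   # (npts, L+1)
        inv = np.divide(r1, r, out=np.zeros_like(r), where=r > 0)
        ww = np.power.outer(inv, lsf + 1.0)
        ww[r == 0] = 0.0
    # radial factor per point: A/B of the point's layer; in layer 1 the
    # (singular) source part is replaced by the exact infinite-medium term
    radial = A[layer] * uu + B[layer] * ww
    in1 = layer == 1
    radial[in1] = A[1][None, :] * uu[in1]
    out = np.einsum("il,l,il->i", radial, bz, P) \
        + np.einsum("il,l,il->i", radial, bt, P1) * tang
    if in1.any():
        d = points[in1] - r0
        dn = np.linalg.norm(d, axis=1)
        out[in1] += (d @ q) / (4 * np.pi * sig[0] * dn ** 3)
    # actual magnitude of the last retained term per point
    tail = float(np.max(np.abs(radial[:, L]) * (
        np.abs(bz[L] * P[:, L]) + np.abs(bt[L] * P1[:, L] * tang))))
    scale = np.abs(out).max() if np.abs(out).max() > 0 else 1.0
    if tail > 1e-8 * scale:
        warnings.warn("sphere series may not be converged at L="
                      f"{L} (last term {tail:.2e})", stacklevel=2)
    return out


def eeg_sphere_potential(model: SphereModel, dipole_pos, dipole_mom,
                         points, zero_mean: bool = True) -> np.ndarray:
    """Surface/interior potential of a dipole in the innermost layer.

    Zero-mean referenced over the evaluation set by default (the potential
    is defined up to an additive constant)."""
    v = _evaluate_series(model, dipole_pos, dipole_mom, points, model.L)
    if zero_mean:
        v = v - v.mean()
    return v


def ip_sphere_potential(model: SphereModel, dipole_pos, dipole_mom,
                        points, zero_mean: bool = True) -> np.ndarray:
    """Alias of the series evaluation at interior points."""
    return eeg_sphere_potential(model, dipole_pos, dipole_mom, points,
                                zero_mean=zero_mean)


def meg_sphere_field(dipole_pos, dipole_mom, points,
                     directions=None) -> np.ndarray:
    """Magnetic field of a dipole in a spherically symmetric conductor.

    Independent of the layer radii and conductivities.  Returns the (n, 3)
    field, or directional readings when ``directions`` is given.  Radial
    dipoles are magnetically silent.
    """
    r0 = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(dipole_mom, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    a_vec = pts - r0
    a = np.linalg.norm(a_vec, axis=1)
    if (a < 1e-12).any() or (r < 1e-12).any():
        raise ValueError("sensor coincides with the dipole or the origin")
    F = a * (r * a + r ** 2 - pts @ r0)
    if (np.abs(F) < 1e-20).any():
        raise ValueError("sensor on the dipole ray: formula degenerate")
    # grad F
    gF = ((a ** 2 / r + (a_vec * pts).sum(axis=1) / a + 2 * a + 2 * r)[:, None]
          * pts
          - (a + 2 * r + (a_vec * pts).sum(axis=1) / a)[:, None] * r0)
    qxr0 = np.cross(q, r0)
    B = (MU0 / (4 * np.pi * F ** 2))[:, None] * (
        F[:, None] * qxr0 - (pts @ qxr0)[:, None] * gF)
    if directions is None:
        return B
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    return np.einsum("ij,ij->i", B, directions)


# ---------------------------------------------------------------------------
# EIT (Neumann boundary data)
# ---------------------------------------------------------------------------

def eit_sphere_potential(model: SphereModel, injection_triangles,
                         injection_densities, points,
                         zero_mean: bool = True,
                         quad_points: int = 7,
                         subdivisions: int = 2) -> np.ndarray:
    """Potential from boundary current injection, by separation of variables.

    ``injection_triangles`` is a list of (3, 3) corner arrays approximating
    patches of the outer sphere and ``injection_densities`` the uniform
    current density (A/m^2, convention sigma dV/dn = j) on each; the total
    injected current must vanish.  ``points`` are evaluated anywhere inside.
    """
    from ._kernels import gauss_rule

    rho = np.array(model.radii)
    sig = np.array(model.conductivities)
    N = model.n_layers
    L = model.L
    rN, r1 = rho[-1], rho[0]
    tris = [np.asarray(t, dtype=float) for t in injection_triangles]
    dens = np.asarray(injection_densities, dtype=float)
    if len(tris) != len(dens):
        raise ValueError("one density per injection triangle")
    total = sum(d * 0.5 * np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0]))
                for t, d in zip(tris, dens))
    scale = max(abs(dens).max(), 1e-300) * rN ** 2
    if abs(total) > 1e-9 * scale:
        raise ValueError(f"net injected current {total:.3e} must be zero")

    qb, qw = gauss_rule(quad_points)
    # project the flat-triangle current onto spherical harmonics:
    # j_lm = int j(r') Y_lm(r'^) dS'.  Triangles are uniformly subdivided
    # first so the quadrature resolves Y_lm oscillations up to degree L.
    def subdivide(t, k):
        if k == 0:
            return [t]
        m01, m12, m20 = ((t[0] + t[1]) / 2, (t[1] + t[2]) / 2,
                         (t[2] + t[0]) / 2)
        subs = [np.array([t[0], m01, m20]), np.array([t[1], m12, m01]),
                np.array([t[2], m20, m12]), np.array([m01, m12, m20])]
        return [s for sub in subs for s in subdivide(sub, k - 1)]

    qpts = []
    qwts = []
    for t0, d in zip(tris, dens):
        for t in subdivide(t0, subdivisions):
            area = 0.5 * np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0]))
            qpts.append(qb @ t)
            qwts.append(d * area * qw)
    qpts = np.concatenate(qpts)
    qwts = np.concatenate(qwts)
    # complex expansion of the (real) boundary data: j = sum a_lm Y_lm with
    # a_lm = int j conj(Y_lm) dS / rN^2
    a_lm = _harmonic_projection(L, qpts, qwts) / rN ** 2
    a_lm[0, :] = 0.0  # the l = 0 mode is an undetermined constant

    points = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(points, axis=1)
    layer = np.minimum(np.searchsorted(rho * (1 + 1e-9), r) + 1, N)

    # radial transfer per degree: f_i = A_i (r/rN)^l + B_i (r1/r)^(l+1)
    # with B_1 = 0 and Neumann data sigma_N f'(rN) = 1 (scaled by a_lm)
    Acof = np.zeros((N + 1, L + 1))
    Bcof = np.zeros((N + 1, L + 1))
    for l in range(1, L + 1):
        nun = 2 * N - 1
        M = np.zeros((nun, nun))
        rhs = np.zeros(nun)

        def idx_A(i):
            return 0 if i == 1 else 2 * i - 3

        def idx_B(i):
            return 2 * i - 2

        def u(rr):
            return (rr / rN) ** l, l * (rr / rN) ** l / rr

        def w(rr):
            return (r1 / rr) ** (l + 1), -(l + 1) * (r1 / rr) ** (l + 1) / rr

        row = 0
        for i in range(1, N):
            rr = rho[i - 1]
            uv, ud = u(rr)
            wv, wd = w(rr)
            M[row, idx_A(i)] += uv
            if i > 1:
                M[row, idx_B(i)] += wv
            M[row, idx_A(i + 1)] -= uv
            M[row, idx_B(i + 1)] -= wv
            row += 1
            M[row, idx_A(i)] += sig[i - 1] * ud
            if i > 1:
                M[row, idx_B(i)] += sig[i - 1] * wd
            M[row, idx_A(i + 1)] -= sig[i] * ud
            M[row, idx_B(i + 1)] -= sig[i] * wd
            row += 1
        uv, ud = u(rN)
        wv, wd = w(rN)
        M[row, idx_A(N)] += sig[-1] * ud
        if N > 1:
            M[row, idx_B(N)] += sig[-1] * wd
        rhs[row] = 1.0
        sol = np.linalg.solve(M, rhs)
        Acof[1, l] = sol[0]
        for i in range(2, N + 1):
            Acof[i, l] = sol[idx_A(i)]
            Bcof[i, l] = sol[idx_B(i)]

    lsf = np.arange(L + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        uu = np.power.outer(r / rN, lsf)
        inv = np.divide(r1, r, out=np.zeros_like(r), where=r > 0)
        ww = np.power.outer(inv, lsf + 1.0)
        ww[r == 0] = 0.0
    radial = Acof[layer] * uu + np.where(Bcof[layer] == 0.0, 0.0,
                                         Bcof[layer] * ww)
    out = _harmonic_evaluate(a_lm, radial, points)
    if zero_mean:
        out = out - out.mean()
    return out


def _harmonic_projection(L, pts, wts):
    """sum_i w_i conj(Y_lm)(x_i^) as an (L+1, 2L+1) complex array."""
    from scipy.special import sph_harm_y_all

    r = np.linalg.norm(pts, axis=1)
    theta = np.arccos(np.clip(pts[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    out = np.zeros((L + 1, 2 * L + 1), dtype=complex)
    chunk = max(1, int(6e7 // max((L + 1) * (2 * L + 1), 1)))
    for s in range(0, len(pts), chunk):
        sl = slice(s, min(s + chunk, len(pts)))
        y = sph_harm_y_all(L, L, theta[sl], phi[sl])
        out += np.conj(y) @ wts[sl]
    return out


def _harmonic_evaluate(coef, radial, points):
    """Re sum_lm coef_lm radial_l(x) Y_lm(x) per point."""
    from scipy.special import sph_harm_y_all

    L = coef.shape[0] - 1
    points = np.atleast_2d(points)
    r = np.linalg.norm(points, axis=1)
    ct = np.divide(points[:, 2], r, out=np.zeros_like(r), where=r > 0)
    theta = np.arccos(np.clip(ct, -1.0, 1.0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    out = np.empty(len(points))
    chunk = max(1, int(6e7 // max((L + 1) * (2 * L + 1), 1)))
    for s in range(0, len(points), chunk):
        sl = slice(s, min(s + chunk, len(points)))
        y = sph_harm_y_all(L, L, theta[sl], phi[sl])
        out[sl] = np.einsum("lm,lmp,pl->p", coef, y, radial[sl]).real
    return out
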
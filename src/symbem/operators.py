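"""Galerkin boundary integral operators on triangulated surfaces.

Conventions (outward unit normals everywhere, G(r,r') = 1/(4*pi*||r-r'||)):

* single layer   S(psi_k, psi_l) = int int G                (P0 x P0)
* double layer   D(psi_k, phi_j) = int int dG/dn' phi_j     (P0 x P1),
  principal value on a common surface (coplanar pairs contribute zero);
  the adjoint D* is the transposed block.
* hypersingular  N(phi_i, phi_j) = int int G (n x grad phi_i).(n' x grad
  phi_j), the integration-by-parts (surface curl) weak form.  This block is
  symmetric positive semidefinite with the constants as kernel; the Galerkin
  form of the normal-derivative operator d/dn D is its negative.

Singular and near-singular inner integrals use closed forms over flat
triangles; outer integrals use a symmetric Gauss rule with optional adaptive
subdivision (recursive 1:4 refinement until the relative change between
levels drops below the tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import _kernels as K
from .mesh import TriangleMesh

__all__ = [
    "BasisSpace",
    "OperatorBlock",
    "QuadratureConfig",
    "assemble_single_layer",
    "assemble_double_layer",
    "assemble_hypersingular",
    "analytic_triangle_integrals",
    "adaptive_integrate",
    "mass_matrix",
]

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class BasisSpace:
    """P0 (per-triangle constant) or P1 (per-vertex linear) boundary space."""

    mesh: TriangleMesh
    order: str  # "P0" or "P1"

    def __post_init__(self):
        if self.order not in ("P0", "P1"):
            raise ValueError("order must be 'P0' or 'P1'")

    @property
    def dimension(self) -> int:
        return (self.mesh.n_triangles if self.order == "P0"
                else self.mesh.n_vertices)


@dataclass(frozen=True)
class OperatorBlock:
    matrix: np.ndarray
    row_space: BasisSpace
    col_space: BasisSpace
    tag: str  # one of S, D, D*, N, mass

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        expected = (self.row_space.dimension, self.col_space.dimension)
        if m.shape != expected:
            raise ValueError(f"block shape {m.shape} != {expected}")
        if not np.isfinite(m).all():
            raise ValueError("non-finite operator entries")
        object.__setattr__(self, "matrix", m)

    @property
    def T(self) -> "OperatorBlock":
        tag = {"D": "D*", "D*": "D"}.get(self.tag, self.tag)
        return OperatorBlock(self.matrix.T, self.col_space, self.row_space,
                             tag)


@dataclass(frozen=True)
class QuadratureConfig:
    """Outer-integration configuration.

    ``n_points`` selects the base symmetric Gauss rule (1, 3 or 7 points;
    the 7-point rule is exact through degree 5).  With ``adaptive`` on,
    near pairs are refined by recursive subdivision until the relative
    change between levels is below ``tol`` or ``max_depth`` is reached; with
    it off a single base-rule pass is used everywhere (OMNA mode).
    ``far_factor`` scales the near-pair detection radius.
    """

    n_points: int = 7
    adaptive: bool = True
    tol: float = 1e-4
    max_depth: int = 10
    far_factor: float = 2.0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")

    @cached_property
    def rule(self):
        return K.gauss_rule(self.n_points)


DEFAULT_QUAD = QuadratureConfig()

_pack_cache: dict[int, tuple] = {}


def _pack(mesh: TriangleMesh):
    # keyed by id() but storing the mesh itself, so a recycled id of a
    # garbage-collected mesh cannot alias a stale entry
    key = id(mesh)
    hit = _pack_cache.get(key)
    if hit is None or hit[0] is not mesh:
        if len(_pack_cache) > 64:
            _pack_cache.clear()
        _pack_cache[key] = (mesh, K.triangle_precompute(mesh))
        hit = _pack_cache[key]
    return hit[1]


def _check_distinct(mesh_a: TriangleMesh, mesh_b: TriangleMesh):
    if mesh_a is mesh_b:
        return True  # same surface: singular pairs handled analytically
    same = (mesh_a.n_vertices == mesh_b.n_vertices
            and np.array_equal(mesh_a.vertices, mesh_b.vertices)
            and np.array_equal(mesh_a.triangles, mesh_b.triangles))
    if same:
        return True
    # coincident but non-identical surfaces are not supported
    da = np.linalg.norm(mesh_a.centroids[:, None, :]
                        - mesh_b.centroids[None, :, :], axis=2)
    if da.min() < 1e-12 * max(mesh_a.bounding_radius(), 1e-300):
        raise ValueError("distinct surfaces coincide (distance 0)")
    return False


def raw_ss(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
           quad: QuadratureConfig = DEFAULT_QUAD,
           pair_mode: int = 0) -> np.ndarray:
    """Raw triangle-pair integrals int_Tk int_Tl 1/R (no 1/4pi).

    ``pair_mode`` restricts the computed pairs (0 = all, 1 = far only,
    2 = near only) so assemblies differing only in near-pair treatment can
    share the far-pair work.
    """
    same = _check_distinct(mesh_a, mesh_b)
    cornA, _, _, _, _, scaleA = _pack(mesh_a)
    cornB, shatB, mhatB, nhatB, _, scaleB = _pack(mesh_b)
    qb, qw = quad.rule
    return K.galerkin_ss(
        np.ascontiguousarray(mesh_a.centroids), scaleA, cornA,
        np.ascontiguousarray(mesh_b.centroids), scaleB, cornB,
        shatB, mhatB, nhatB, qb, qw,
        quad.adaptive, quad.tol, quad.max_depth, quad.far_factor, same,
        pair_mode)


def raw_d(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
          quad: QuadratureConfig = DEFAULT_QUAD,
          pair_mode: int = 0) -> np.ndarray:
    """Raw (nTA, nVB) double-layer Galerkin integrals (times 4pi)."""
    same = _check_distinct(mesh_a, mesh_b)
    cornA, _, _, _, _, scaleA = _pack(mesh_a)
    cornB, shatB, mhatB, nhatB, gradsB, scaleB = _pack(mesh_b)
    qb, qw = quad.rule
    return K.galerkin_d(
        np.ascontiguousarray(mesh_a.centroids), scaleA, cornA,
        np.ascontiguousarray(mesh_b.centroids), scaleB, cornB,
        shatB, mhatB, nhatB, gradsB,
        np.ascontiguousarray(mesh_b.triangles), mesh_b.n_vertices,
        qb, qw, quad.adaptive, quad.tol, quad.max_depth, quad.far_factor,
        same, pair_mode)


def assemble_single_layer(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
                          quad: QuadratureConfig = DEFAULT_QUAD
                          ) -> OperatorBlock:
    """P0 x P0 single-layer block; self-surface blocks are SPD."""
    m = raw_ss(mesh_a, mesh_b, quad) / FOUR_PI
    return OperatorBlock(m, BasisSpace(mesh_a, "P0"),
                         BasisSpace(mesh_b, "P0"), "S")


def assemble_double_layer(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
                          quad: QuadratureConfig = DEFAULT_QUAD
                          ) -> tuple[OperatorBlock, OperatorBlock]:
    """P0_a x P1_b double-layer block and its adjoint (transpose)."""
    m = raw_d(mesh_a, mesh_b, quad) / FOUR_PI
    block = OperatorBlock(m, BasisSpace(mesh_a, "P0"),
                          BasisSpace(mesh_b, "P1"), "D")
    return block, block.T


def p1_curl_map(mesh: TriangleMesh) -> list:
    """Three sparse (n_vertices, n_triangles) matrices Q_x, Q_y, Q_z with
    Q[i, T] = (n_T x grad phi_i|_T) so that the curl-form hypersingular
    block is sum_c Q_c SS Q_c^T."""
    from scipy.sparse import csr_matrix

    p0, p1, p2 = mesh.corners
    areas = mesh.areas
    # n x grad phi_j = -(opposite edge)/(2 A)
    opp = np.stack([p2 - p1, p0 - p2, p1 - p0], axis=1)
    qvec = -opp / (2.0 * areas[:, None, None])
    nt, nv = mesh.n_triangles, mesh.n_vertices
    out = []
    rows = mesh.triangles.ravel()
    cols = np.repeat(np.arange(nt), 3)
    for c in range(3):
        Q = csr_matrix((qvec[:, :, c].ravel(), (rows, cols)),
                       shape=(nv, nt))
        out.append(Q)
    return out


def assemble_hypersingular(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
                           quad: QuadratureConfig = DEFAULT_QUAD,
                           ss: np.ndarray | None = None) -> OperatorBlock:
    """P1 x P1 surface-curl weak form of the hypersingular operator.

    Self blocks are symmetric positive semidefinite and annihilate
    constants exactly (the per-triangle curls of the P1 partition of unity
    sum to zero).  Pass a precomputed ``raw_ss`` matrix to avoid recomputing
    the triangle-pair integrals.
    """
    if ss is None:
        ss = raw_ss(mesh_a, mesh_b, quad)
    qa = p1_curl_map(mesh_a)
    qb = p1_curl_map(mesh_b)
    m = np.zeros((mesh_a.n_vertices, mesh_b.n_vertices))
    for c in range(3):
        m += qa[c] @ ss @ qb[c].T
    m /= FOUR_PI
    if mesh_a is mesh_b:
        m = 0.5 * (m + m.T)
    return OperatorBlock(m, BasisSpace(mesh_a, "P1"),
                         BasisSpace(mesh_b, "P1"), "N")


def analytic_triangle_integrals(point, triangle: np.ndarray):
    """Closed-form single/double-layer potentials of one flat triangle.

    Returns ``(s, d)`` where ``s = int_T G(point, r') dS'`` and ``d`` holds
    ``int_T dG/dn'(point, r') phi_j(r') dS'`` for the three local vertices
    (principal-value convention: zero when the point lies in the triangle's
    plane).
    """
    tri = np.asarray(triangle, dtype=np.float64)
    if tri.shape != (3, 3):
        raise ValueError("triangle must be a (3, 3) corner array")
    mesh = TriangleMesh(tri, np.array([[0, 1, 2]]))
    pts = np.atleast_2d(np.asarray(point, dtype=np.float64))
    corn, shat, mhat, nhat, grads, scale = K.triangle_precompute(mesh)
    s, d = K.point_sd(np.ascontiguousarray(pts), corn, shat, mhat, nhat,
                      grads, scale, np.ascontiguousarray(mesh.triangles), 3)
    return s[0, 0] / FOUR_PI, d[0] / FOUR_PI


def adaptive_integrate(func, triangle, quad: QuadratureConfig = DEFAULT_QUAD):
    """Integrate ``func(points) -> values`` over one triangle.

    Recursive 1:4 subdivision until the relative change between levels is
    below ``quad.tol`` or ``quad.max_depth`` is reached (a warning flag is
    returned alongside the value); with ``quad.adaptive`` off, a single
    base-rule pass.
    """
    tri = np.asarray(triangle, dtype=np.float64)
    qb, qw = quad.rule

    def one_pass(t):
        area = 0.5 * np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0]))
        pts = qb @ t
        return area * float(qw @ np.asarray(func(pts), dtype=float))

    coarse = one_pass(tri)
    if not quad.adaptive:
        return coarse, False

    warn = [False]

    def split(t):
        m01, m12, m20 = ((t[0] + t[1]) / 2, (t[1] + t[2]) / 2,
                         (t[2] + t[0]) / 2)
        subs = [np.array([t[0], m01, m20]), np.array([t[1], m12, m01]),
                np.array([t[2], m20, m12]), np.array([m01, m12, m20])]
        return subs, [one_pass(s) for s in subs]

    def refine(t, coarse_val, depth):
        subs, parts = split(t)
        fine = sum(parts)
        if abs(fine - coarse_val) <= quad.tol * abs(fine) + 1e-300:
            return fine
        if depth >= quad.max_depth:
            warn[0] = True
            return fine
        return sum(refine(s, p, depth + 1) for s, p in zip(subs, parts))

    # a smooth integrand converged at the first check keeps the base-rule
    # value (no subdivision is triggered beyond the first level)
    subs, parts = split(tri)
    fine = sum(parts)
    if abs(fine - coarse) <= quad.tol * abs(fine) + 1e-300:
        return coarse, False
    if quad.max_depth == 0:
        return fine, True
    return sum(refine(s, p, 1) for s, p in zip(subs, parts)), warn[0]


def mass_matrix(space_a: BasisSpace, space_b: BasisSpace) -> OperatorBlock:
    """Exact Galerkin products of P0/P1 bases on one mesh."""
    if space_a.mesh is not space_b.mesh and not (
            np.array_equal(space_a.mesh.vertices, space_b.mesh.vertices)
            and np.array_equal(space_a.mesh.triangles,
                               space_b.mesh.triangles)):
        raise ValueError("mass matrix requires both spaces on the same mesh")
    mesh = space_a.mesh
    areas = mesh.areas
    tris = mesh.triangles
    nv, nt = mesh.n_vertices, mesh.n_triangles
    oa, ob = space_a.order, space_b.order
    if (oa, ob) == ("P0", "P0"):
        m = np.diag(areas)
    elif (oa, ob) == ("P1", "P1"):
        m = np.zeros((nv, nv))
        for i in range(3):
            for j in range(3):
                np.add.at(m, (tris[:, i], tris[:, j]),
                          areas * (1 / 6 if i == j else 1 / 12))
    else:
        m = np.zeros((nv, nt))
        np.add.at(m, (tris.ravel(), np.repeat(np.arange(nt), 3)),
                  np.repeat(areas / 3.0, 3))
        if oa == "P0":
            m = m.T
    return OperatorBlock(m, space_a, space_b, "mass")
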
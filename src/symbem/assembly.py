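"""Assembly of the symmetric block system and all sensor-side matrices.

Unknowns are ordered per interface, innermost first: the P1-discretized
potential V_i on S_i, then (except on the scalp, where the normal current
vanishes) the P0-discretized normal current p_i = (sigma dV/dn)_{S_i}.

Block recipe (outward normals; S, D, N as in :mod:`symbem.operators`; the
normal-derivative double layer is the negative of the curl-form N):

    (V_i, V_i)     -(sigma_i + sigma_{i+1}) N_ii        (sigma_{N+1} = 0)
    (V_i, V_{i+1}) +sigma_{i+1} N_{i,i+1}
    (p_i, p_i)     +(1/sigma_i + 1/sigma_{i+1}) S_ii
    (p_i, p_{i+1}) -(1/sigma_{i+1}) S_{i,i+1}
    (p_i, V_i)     -2 D_ii           (V_i, p_i) the transpose
    (p_i, V_{i+1}) +D_{i,i+1}        and symmetrically for i-1

A rank-one deflation on the scalp V block removes the constant null space.
For a dipole in domain j with infinite-medium potential v (conductivity
sigma_j), the right-hand side is

    V rows of S_j:     +sigma_j <phi, dv/dn>     S_{j-1}: the negative
    p rows of S_j:     -<psi, v>                 S_{j-1}: the positive

all other rows zero; EIT moves the known scalp current to the right-hand
side, and the internal-potential rows evaluate the Green representation of
V inside its domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .mesh import (DipoleSet, EITInjection, HeadModel, SensorSet,
                   SurfaceSource, TriangleMesh, locate_domain)
from .operators import (DEFAULT_QUAD, FOUR_PI, BasisSpace, QuadratureConfig,
                        _pack, mass_matrix, p1_curl_map, raw_ss)

__all__ = [
    "BlockIndexMap",
    "HeadMatrix",
    "HeadMatrixDecomposition",
    "SourceMatrix",
    "TransferMatrix",
    "assemble_head_matrix",
    "assemble_dipole_source_matrix",
    "assemble_surface_source_matrix",
    "assemble_eit_source_matrix",
    "head2eeg",
    "head2meg",
    "head2ip",
    "dipsource2meg",
    "surfsource2meg",
    "dipsource2ip",
    "infinite_medium_potential",
]

MU0 = 4.0e-7 * np.pi


@dataclass(frozen=True)
class BlockIndexMap:
    """Slices of the boundary unknown vector: V_i for every interface,
    p_i for every interface but the scalp."""

    v_slices: tuple[slice, ...]
    p_slices: tuple[slice | None, ...]
    total: int

    @classmethod
    def for_model(cls, model: HeadModel) -> "BlockIndexMap":
        v_slices = []
        p_slices = []
        off = 0
        n = model.n_interfaces
        for i, surf in enumerate(model.interfaces):
            v_slices.append(slice(off, off + surf.n_vertices))
            off += surf.n_vertices
            if i < n - 1:
                p_slices.append(slice(off, off + surf.n_triangles))
                off += surf.n_triangles
            else:
                p_slices.append(None)
        return cls(tuple(v_slices), tuple(p_slices), off)

    def v(self, i: int) -> slice:
        """V slice of interface i (1-based)."""
        return self.v_slices[i - 1]

    def p(self, i: int) -> slice:
        s = self.p_slices[i - 1]
        if s is None:
            raise IndexError("the scalp has no normal-current block")
        return s


@dataclass
class HeadMatrix:
    matrix: np.ndarray
    index: BlockIndexMap
    model: HeadModel
    deflation_vector: np.ndarray | None = None
    deflation_coefficient: float = 0.0

    @property
    def n(self) -> int:
        return self.index.total


@dataclass
class HeadMatrixDecomposition:
    """H(sigma) = C + sum_i (sigma_i A_i + B_i / sigma_i).

    C holds the conductivity-independent double-layer blocks plus the
    deflation term; A_i / B_i hold the hypersingular / single-layer blocks
    of the two interfaces bounding domain i.
    """

    constant: np.ndarray
    A: list[np.ndarray]
    B: list[np.ndarray]
    index: BlockIndexMap

    def assemble(self, sigmas) -> np.ndarray:
        h = self.constant.copy()
        for s, a, b in zip(sigmas, self.A, self.B):
            h += s * a + b / s
        return h


@dataclass
class SourceMatrix:
    matrix: np.ndarray
    index: BlockIndexMap
    kind: str  # "dipole" | "surface" | "eit"


@dataclass
class TransferMatrix:
    matrix: np.ndarray
    kind: str  # Head2EEG, Head2MEG, Head2IP, Source2MEG, Source2IP
    sensors: SensorSet | None = None


# ---------------------------------------------------------------------------
# operator caching per (model, quadrature)
# ---------------------------------------------------------------------------

class OperatorCache:
    """Caches raw triangle-pair integrals and assembled operator blocks for
    one head model and one quadrature configuration.

    ``far_cache`` enables paired assemblies: when given, this cache computes
    only the near pairs (adaptively or not, per ``quad``) and adds the far
    pairs from the shared cache, so that an adaptive and a non-adaptive
    assembly reuse identical far-field work.
    """

    def __init__(self, model: HeadModel,
                 quad: QuadratureConfig = DEFAULT_QUAD,
                 far_cache: "OperatorCache | None" = None):
        self.model = model
        self.quad = quad
        self.far_cache = far_cache
        self._pair_mode = 0 if far_cache is None else 2
        self._ss: dict[tuple[int, int], np.ndarray] = {}
        self._d: dict[tuple[int, int], np.ndarray] = {}
        self._n: dict[tuple[int, int], np.ndarray] = {}

    @classmethod
    def far_only(cls, model: HeadModel, quad: QuadratureConfig):
        c = cls(model, quad)
        c._pair_mode = 1
        return c

    def ss(self, a: int, b: int) -> np.ndarray:
        """Raw int int 1/R between interfaces a, b (1-based)."""
        if (a, b) in self._ss:
            return self._ss[(a, b)]
        if (b, a) in self._ss:
            m = self._ss[(b, a)].T
        else:
            m = raw_ss(self.model.interfaces[a - 1],
                       self.model.interfaces[b - 1], self.quad,
                       pair_mode=self._pair_mode)
            if self.far_cache is not None:
                m = m + self.far_cache.ss(a, b)
        self._ss[(a, b)] = m
        return m

    def S(self, a: int, b: int) -> np.ndarray:
        return self.ss(a, b) / FOUR_PI

    def N(self, a: int, b: int) -> np.ndarray:
        """Curl-form (positive semidefinite self) hypersingular block."""
        if (a, b) not in self._n:
            if (b, a) in self._n:
                self._n[(a, b)] = self._n[(b, a)].T
            else:
                ma = self.model.interfaces[a - 1]
                mb = self.model.interfaces[b - 1]
                qa = p1_curl_map(ma)
                qb = p1_curl_map(mb)
                ss = self.ss(a, b)
                m = np.zeros((ma.n_vertices, mb.n_vertices))
                for c in range(3):
                    m += qa[c] @ ss @ qb[c].T
                m /= FOUR_PI
                if a == b:
                    m = 0.5 * (m + m.T)
                self._n[(a, b)] = m
        return self._n[(a, b)]

    def D(self, a: int, b: int) -> np.ndarray:
        """P0_a x P1_b Galerkin double layer."""
        if (a, b) not in self._d:
            from .operators import raw_d

            m = raw_d(self.model.interfaces[a - 1],
                      self.model.interfaces[b - 1], self.quad,
                      pair_mode=self._pair_mode)
            if self.far_cache is not None:
                m = m + self.far_cache._raw_d(a, b)
            self._d[(a, b)] = m / FOUR_PI
        return self._d[(a, b)]

    def _raw_d(self, a: int, b: int) -> np.ndarray:
        from .operators import raw_d

        key = ("rawd", a, b)
        if key not in self._d:
            self._d[key] = raw_d(self.model.interfaces[a - 1],
                                 self.model.interfaces[b - 1], self.quad,
                                 pair_mode=self._pair_mode)
        return self._d[key]


# ---------------------------------------------------------------------------
# head matrix
# ---------------------------------------------------------------------------

def _deflation(model: HeadModel, index: BlockIndexMap, h_unit: np.ndarray):
    """Rank-one mass-lumped deflation vector on the scalp V block.

    The coefficient is trace-scaled from the unit-conductivity assembly so
    that it does not depend on the conductivities: the decomposition
    reassembly then reproduces a direct assembly entrywise.
    """
    n = model.n_interfaces
    m = np.zeros(index.total)
    scalp = model.interfaces[n - 1]
    m[index.v(n)] = scalp.vertex_areas()
    omega = float(np.trace(np.abs(h_unit))) / index.total / float(m @ m)
    return m, omega


def assemble_head_matrix(model: HeadModel,
                         quad: QuadratureConfig = DEFAULT_QUAD,
                         cache: OperatorCache | None = None,
                         decompose: bool = False,
                         check: bool = True):
    """Assemble the symmetric (deflated) head matrix.

    Only one triangle of each off-diagonal block pair is assembled and
    mirrored, so ``H == H.T`` exactly.  Returns a :class:`HeadMatrix`, or a
    ``(HeadMatrix, HeadMatrixDecomposition)`` pair with ``decompose``.
    """
    if check:
        from .mesh import check_nesting, validate_mesh
        for i, surf in enumerate(model.interfaces):
            rep = validate_mesh(surf)
            if not rep.ok:
                raise ValueError(f"interface {i + 1} invalid: {rep.messages}")
        ok, rep = check_nesting(model)
        if not ok:
            raise ValueError(f"interfaces are not strictly nested: {rep}")
    cache = cache or OperatorCache(model, quad)
    index = BlockIndexMap.for_model(model)
    n = model.n_interfaces
    ntot = index.total

    def sig(i):
        return model.sigma(i)

    # conductivity-dependent parts, organised per domain for the
    # decomposition: domain i touches S_{i-1} (inner boundary) and S_i
    A = [np.zeros((ntot, ntot)) for _ in range(n)]
    B = [np.zeros((ntot, ntot)) for _ in range(n)]
    C = np.zeros((ntot, ntot))

    for i in range(1, n + 1):  # domain i, boundaries S_{i-1}, S_i
        dom = i - 1  # python index into A/B
        a = A[dom]
        b = B[dom]
        # outer boundary S_i always exists
        a[index.v(i), index.v(i)] += -cache.N(i, i)
        if index.p_slices[i - 1] is not None:
            b[index.p(i), index.p(i)] += cache.S(i, i)
        if i >= 2:  # inner boundary S_{i-1}
            a[index.v(i - 1), index.v(i - 1)] += -cache.N(i - 1, i - 1)
            b[index.p(i - 1), index.p(i - 1)] += cache.S(i - 1, i - 1)
            # coupling between the two boundaries of domain i
            nbl = -cache.N(i - 1, i)
            a[index.v(i - 1), index.v(i)] += -nbl
            a[index.v(i), index.v(i - 1)] += -nbl.T
            if index.p_slices[i - 1] is not None \
                    and index.p_slices[i - 2] is not None:
                sbl = cache.S(i - 1, i)
                b[index.p(i - 1), index.p(i)] += -sbl
                b[index.p(i), index.p(i - 1)] += -sbl.T

    # conductivity-independent double-layer blocks
    for i in range(1, n + 1):
        if index.p_slices[i - 1] is not None:
            d = cache.D(i, i)
            C[index.p(i), index.v(i)] += -2.0 * d
            C[index.v(i), index.p(i)] += -2.0 * d.T
        if i >= 2:
            if index.p_slices[i - 2] is not None:
                d = cache.D(i - 1, i)  # p_{i-1} rows, V_i columns
                C[index.p(i - 1), index.v(i)] += d
                C[index.v(i), index.p(i - 1)] += d.T
            if index.p_slices[i - 1] is not None:
                d = cache.D(i, i - 1)
                C[index.p(i), index.v(i - 1)] += d
                C[index.v(i - 1), index.p(i)] += d.T

    h = C.copy()
    h_unit = C.copy()
    for i in range(n):
        h += sig(i + 1) * A[i] + B[i] / sig(i + 1)
        h_unit += A[i] + B[i]

    m, omega = _deflation(model, index, h_unit)
    h = h + omega * np.outer(m, m)
    hm = HeadMatrix(h, index, model, deflation_vector=m,
                    deflation_coefficient=omega)
    if decompose:
        Cd = C + omega * np.outer(m, m)
        return hm, HeadMatrixDecomposition(Cd, A, B, index)
    return hm


# ---------------------------------------------------------------------------
# dipole sources
# ---------------------------------------------------------------------------

def infinite_medium_potential(positions, moments, points, sigma: float,
                              gradient: bool = False):
    """Potential v(r) = q.(r - r0) / (4 pi sigma ||r - r0||^3) of dipoles in
    an unbounded homogeneous medium (and optionally its gradient).

    ``positions``/``moments`` are (nd, 3); ``points`` (np, 3).  Returns
    (np, nd) potentials, plus (np, nd, 3) gradients if requested.
    """
    r0 = np.atleast_2d(np.asarray(positions, float))
    q = np.atleast_2d(np.asarray(moments, float))
    pts = np.atleast_2d(np.asarray(points, float))
    d = pts[:, None, :] - r0[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", d, d)
    if (r2 < 1e-30).any():
        raise ValueError("evaluation point coincides with a dipole")
    r = np.sqrt(r2)
    r3 = r2 * r
    qd = np.einsum("ijk,jk->ij", d, q)
    v = qd / (FOUR_PI * sigma * r3)
    if not gradient:
        return v
    g = (q[None, :, :] / r3[:, :, None]
         - 3.0 * qd[:, :, None] * d / (r3 * r2)[:, :, None])
    return v, g / (FOUR_PI * sigma)


def assemble_dipole_source_matrix(model: HeadModel, dipoles: DipoleSet,
                                  quad: QuadratureConfig = DEFAULT_QUAD
                                  ) -> SourceMatrix:
    """Right-hand side columns for pointwise dipoles (linear in the moment).

    Only the rows of the interfaces bounding the dipole's domain are
    nonzero.  The P0 rows use exact analytic integrals; the P1 rows use
    (adaptively refined) quadrature of the normal derivative of the
    infinite-medium potential.
    """
    if dipoles.domains is None:
        dipoles = dipoles.resolve(model)
    index = BlockIndexMap.for_model(model)
    out = np.zeros((index.total, len(dipoles)))
    qb, qw = quad.rule
    for c, (r0, q, dom) in enumerate(zip(dipoles.positions, dipoles.moments,
                                         dipoles.domains)):
        sigma_j = model.sigma(int(dom))
        for i, sign in ((int(dom), 1.0), (int(dom) - 1, -1.0)):
            if i < 1:
                continue
            surf = model.interfaces[i - 1]
            corn, shat, mhat, nhat, grads, scale = _pack(surf)
            tris = np.ascontiguousarray(surf.triangles)
            # P1 rows: sign * sigma_j * <phi, dv_dip/dn>
            p1 = K.dipole_p1_integrals(
                np.ascontiguousarray(r0), np.ascontiguousarray(q),
                corn, nhat, grads, tris, surf.n_vertices, qb, qw,
                quad.adaptive, min(quad.tol, 1e-6), quad.max_depth)
            out[index.v(i), c] += sign * p1 / FOUR_PI
            # P0 rows: -sign * <psi, v_dip>, exact
            if index.p_slices[i - 1] is not None:
                p0 = K.dipole_p0_integrals(
                    np.ascontiguousarray(r0), np.ascontiguousarray(q),
                    corn, shat, mhat, nhat, scale)
                out[index.p(i), c] += -sign * p0 / (FOUR_PI * sigma_j)
    return SourceMatrix(out, index, "dipole")


def assemble_surface_source_matrix(model: HeadModel, source: SurfaceSource,
                                   quad: QuadratureConfig = DEFAULT_QUAD
                                   ) -> SourceMatrix:
    """Right-hand side for a surfacic source distribution, one column per
    support vertex (the P1 intensities of the distribution).

    The support mesh must lie strictly inside one domain.  The columns are
    the boundary projections of the double-layer potential generated by each
    P1 dipole-density basis function.
    """
    smesh = source.mesh
    domains = {locate_domain(p, model) for p in smesh.vertices}
    domains |= {locate_domain(p, model) for p in smesh.centroids}
    if len(domains) != 1:
        raise ValueError("surface source crosses an interface "
                         f"(domains {sorted(domains)})")
    dom = domains.pop()
    if dom == 0:
        raise ValueError("surface source lies outside the head")
    sigma_j = model.sigma(dom)
    index = BlockIndexMap.for_model(model)
    out = np.zeros((index.total, smesh.n_vertices))
    qb, qw = quad.rule
    scorn, _, _, snhat, sgrads, _ = _pack(smesh)
    stris = np.ascontiguousarray(smesh.triangles)

    for i, sign in ((dom, 1.0), (dom - 1, -1.0)):
        if i < 1:
            continue
        surf = model.interfaces[i - 1]
        # v(r) = sum_i J_i int phi_i dG/dn' : evaluate per quadrature point
        # of the interface triangles (source mesh strictly inside -> smooth)
        corn = _pack(surf)[0]
        areas = surf.areas
        nhat_s = surf.face_normals
        # P0 rows: -sign/sigma_j * <psi_k, v>
        pts = (qb[None, :, :] @ corn).reshape(-1, 3)  # (nt*nq, 3)
        _, dmat = K.point_sd(np.ascontiguousarray(pts), scorn,
                             *_pack(smesh)[1:4], sgrads, _pack(smesh)[5],
                             stris, smesh.n_vertices)
        v_at = dmat.reshape(surf.n_triangles, len(qw), smesh.n_vertices)
        v_tri = np.einsum("q,tqj->tj", qw, v_at) * areas[:, None] / FOUR_PI
        if index.p_slices[i - 1] is not None:
            out[index.p(i), :] += -sign / sigma_j * v_tri
        # P1 rows: sign * sigma_j * <phi_a, dv/dn>
        grad_v = _surface_source_gradient(pts, smesh)
        ndotg = np.einsum("tk,tqjk->tqj",
                          nhat_s, grad_v.reshape(surf.n_triangles, len(qw),
                                                 smesh.n_vertices, 3))
        phi_w = qb * qw[:, None]  # (nq, 3) quadrature x local P1 value
        contrib = np.einsum("qa,tqj->taj", phi_w, ndotg) * areas[:, None,
                                                                 None]
        block = np.zeros((surf.n_vertices, smesh.n_vertices))
        np.add.at(block, surf.triangles.ravel(),
                  contrib.reshape(-1, smesh.n_vertices))
        out[index.v(i), :] += sign * sigma_j * block
    return SourceMatrix(out, index, "surface")


def _surface_source_gradient(points, smesh: TriangleMesh):
    """Gradient at ``points`` of the double-layer potentials of each P1
    basis function of the source mesh, by quadrature (points off-mesh)."""
    qb, qw = K.gauss_rule(7)
    p0, p1, p2 = smesh.corners
    corn = np.stack([p0, p1, p2], axis=1)
    qpts = qb[None, :, :] @ corn  # (nt, nq, 3)
    areas = smesh.areas
    nhat = smesh.face_normals
    pts = np.asarray(points, float)
    d = pts[:, None, None, :] - qpts[None, :, :, :]  # (np, nt, nq, 3)
    r2 = np.einsum("abcd,abcd->abc", d, d)
    r = np.sqrt(r2)
    r3 = r2 * r
    r5 = r3 * r2
    ndotd = np.einsum("bd,abcd->abc", nhat, d)
    # grad_x [ n'.(x-r')/R^3 ] = n'/R^3 - 3 (n'.(x-r')) (x-r')/R^5
    gker = (nhat[None, :, None, :] / r3[..., None]
            - 3.0 * ndotd[..., None] * d / r5[..., None])
    w = qw[None, None, :] * areas[None, :, None]
    out = np.zeros((len(pts), smesh.n_vertices, 3))
    for a in range(3):
        contrib = np.einsum("abc,abcd->abd", w * qb[None, None, :, a], gker)
        np.add.at(out, (slice(None), smesh.triangles[:, a]), contrib)
    return out / FOUR_PI


# ---------------------------------------------------------------------------
# EIT sources
# ---------------------------------------------------------------------------

def assemble_eit_source_matrix(model: HeadModel,
                               injection: EITInjection,
                               quad: QuadratureConfig = DEFAULT_QUAD,
                               cache: OperatorCache | None = None
                               ) -> SourceMatrix:
    """Right-hand side for boundary current injection (one column per
    stimulation pattern).

    The known scalp current p_N = j (uniform density on each electrode's
    triangle) is moved to the right-hand side:

        V rows of S_N:      (D*_NN - M/2) j
        V rows of S_{N-1}:  -D*_{N-1,N} j
        p rows of S_{N-1}:  +(1/sigma_N) S_{N-1,N} j
    """
    cache = cache or OperatorCache(model, quad)
    index = BlockIndexMap.for_model(model)
    n = model.n_interfaces
    scalp = model.scalp
    areas = scalp.areas
    # P0 coefficient vector of the injected current density per pattern
    j = np.zeros((scalp.n_triangles, injection.n_patterns))
    for e, (tri, cur) in enumerate(zip(injection.triangles,
                                       injection.currents)):
        j[tri, :] += cur / areas[tri]
    out = np.zeros((index.total, injection.n_patterns))
    d_nn = cache.D(n, n)  # P0_N x P1_N
    m_mix = mass_matrix(BasisSpace(scalp, "P1"),
                        BasisSpace(scalp, "P0")).matrix
    out[index.v(n), :] = d_nn.T @ j - 0.5 * (m_mix @ j)
    if n >= 2:
        d_prev = cache.D(n, n - 1)  # P0_N x P1_{N-1}
        out[index.v(n - 1), :] = -(d_prev.T @ j)
        s_prev = cache.S(n - 1, n)
        out[index.p(n - 1), :] = (s_prev @ j) / model.sigma(n)
    return SourceMatrix(out, index, "eit")


# ---------------------------------------------------------------------------
# sensor-side matrices
# ---------------------------------------------------------------------------

def head2eeg(model: HeadModel, electrodes: SensorSet) -> TransferMatrix:
    """Barycentric interpolation of the scalp potential at the electrodes."""
    if electrodes.kind != "EEG" or electrodes.barycentric is None:
        raise ValueError("electrodes must be a projected EEG sensor set")
    index = BlockIndexMap.for_model(model)
    n = model.n_interfaces
    scalp = model.scalp
    out = np.zeros((len(electrodes.positions), index.total))
    vs = index.v(n)
    for e, (tri, bary) in enumerate(zip(electrodes.triangles,
                                        electrodes.barycentric)):
        for local, w in enumerate(bary):
            out[e, vs.start + scalp.triangles[tri, local]] += w
    return TransferMatrix(out, "Head2EEG", electrodes)


def head2meg(model: HeadModel, sensors: SensorSet,
             quad: QuadratureConfig = DEFAULT_QUAD) -> TransferMatrix:
    """Ohmic magnetic field from the boundary potentials.

    B_ohmic(r) = mu0/(4 pi) sum_i (sigma_i - sigma_{i+1})
                 int_{S_i} V(r') (r - r')/||r - r'||^3 x n'(r') dS'.
    """
    if sensors.kind != "MEG":
        raise ValueError("MEG sensor set required")
    index = BlockIndexMap.for_model(model)
    qb, qw = K.gauss_rule(quad.n_points)
    pts = sensors.positions
    dirs = sensors.directions
    wts = sensors.weights
    chans, ch_index = np.unique(sensors.channels, return_inverse=True)
    out = np.zeros((len(chans), index.total))
    for i, surf in enumerate(model.interfaces, start=1):
        dsig = model.sigma(i) - model.sigma(i + 1)
        if dsig == 0.0:
            continue
        p0, p1, p2 = surf.corners
        corn = np.stack([p0, p1, p2], axis=1)
        qpts = qb[None, :, :] @ corn  # (nt, nq, 3)
        nhat = surf.face_normals
        areas = surf.areas
        d = pts[:, None, None, :] - qpts[None, :, :, :]
        r3 = np.einsum("abcd,abcd->abc", d, d) ** 1.5
        ker = np.cross(d / r3[..., None], nhat[None, :, None, :])
        proj = np.einsum("ad,abcd->abc", dirs, ker)  # sensor direction
        w = qw[None, None, :] * areas[None, :, None]
        block = np.zeros((len(pts), surf.n_vertices))
        for a in range(3):
            vals = (w * qb[None, None, :, a] * proj).sum(axis=2)
            np.add.at(block.T, surf.triangles[:, a], vals.T)
        coeff = MU0 / FOUR_PI * dsig
        weighted = coeff * wts[:, None] * block
        np.add.at(out[:, index.v(i)], ch_index, weighted)
    return TransferMatrix(out, "Head2MEG", sensors)


def dipsource2meg(dipoles: DipoleSet, sensors: SensorSet) -> TransferMatrix:
    """Primary (Biot-Savart) field of pointwise dipoles at the sensors."""
    if sensors.kind != "MEG":
        raise ValueError("MEG sensor set required")
    pts = sensors.positions
    d = pts[:, None, :] - dipoles.positions[None, :, :]
    r2 = np.einsum("abc,abc->ab", d, d)
    if (r2 < 1e-30).any():
        raise ValueError("sensor coincides with a dipole")
    r3 = r2 * np.sqrt(r2)
    b = MU0 / FOUR_PI * np.cross(
        np.broadcast_to(dipoles.moments[None, :, :], d.shape), d) \
        / r3[..., None]
    proj = np.einsum("ac,abc->ab", sensors.directions, b)
    proj = sensors.weights[:, None] * proj
    chans, ch_index = np.unique(sensors.channels, return_inverse=True)
    out = np.zeros((len(chans), len(dipoles)))
    np.add.at(out, ch_index, proj)
    return TransferMatrix(out, "Source2MEG", sensors)


def surfsource2meg(source: SurfaceSource, sensors: SensorSet,
                   quad: QuadratureConfig = DEFAULT_QUAD) -> TransferMatrix:
    """Primary field of a surfacic source: one column per support vertex."""
    if sensors.kind != "MEG":
        raise ValueError("MEG sensor set required")
    smesh = source.mesh
    qb, qw = K.gauss_rule(quad.n_points)
    p0, p1, p2 = smesh.corners
    corn = np.stack([p0, p1, p2], axis=1)
    qpts = qb[None, :, :] @ corn
    nhat = smesh.face_normals
    areas = smesh.areas
    pts = sensors.positions
    d = pts[:, None, None, :] - qpts[None, :, :, :]
    r3 = np.einsum("abcd,abcd->abc", d, d) ** 1.5
    # dipole density phi_a n': field mu0/4pi (n' x d)/r^3 per unit density
    ker = np.cross(np.broadcast_to(nhat[None, :, None, :], d.shape),
                   d) / r3[..., None]
    proj = np.einsum("ad,abcd->abc", sensors.directions, ker)
    w = qw[None, None, :] * areas[None, :, None]
    block = np.zeros((len(pts), smesh.n_vertices))
    for a in range(3):
        vals = (w * qb[None, None, :, a] * proj).sum(axis=2)
        np.add.at(block.T, smesh.triangles[:, a], vals.T)
    block *= MU0 / FOUR_PI
    block = sensors.weights[:, None] * block
    chans, ch_index = np.unique(sensors.channels, return_inverse=True)
    out = np.zeros((len(chans), smesh.n_vertices))
    np.add.at(out, ch_index, block)
    return TransferMatrix(out, "Source2MEG", sensors)


# ---------------------------------------------------------------------------
# internal potential
# ---------------------------------------------------------------------------

def head2ip(model: HeadModel, points: SensorSet,
            quad: QuadratureConfig = DEFAULT_QUAD) -> TransferMatrix:
    """Green representation of V at internal points from the boundary data:

    for r in domain m,
      V(r) = v_m(r)/sigma_m - D_{S_m}[V_m](r) + D_{S_{m-1}}[V_{m-1}](r)
             + S_{S_m}[p_m](r)/sigma_m - S_{S_{m-1}}[p_{m-1}](r)/sigma_m
    (the source term v_m is handled by :func:`dipsource2ip`).
    """
    if points.kind != "IP":
        raise ValueError("internal-point sensor set required")
    index = BlockIndexMap.for_model(model)
    out = np.zeros((len(points.positions), index.total))
    n = model.n_interfaces
    for m in range(1, n + 1):
        mask = points.domains == m
        if not mask.any():
            continue
        pts = np.ascontiguousarray(points.positions[mask])
        sigma_m = model.sigma(m)
        for i, sign in ((m, 1.0), (m - 1, -1.0)):
            if i < 1:
                continue
            surf = model.interfaces[i - 1]
            corn, shat, mhat, nhat, grads, scale = _pack(surf)
            s_pt, d_pt = K.point_sd(pts, corn, shat, mhat, nhat, grads,
                                    scale,
                                    np.ascontiguousarray(surf.triangles),
                                    surf.n_vertices)
            out[np.ix_(mask, range(index.v(i).start, index.v(i).stop))] += \
                -sign * d_pt / FOUR_PI
            if index.p_slices[i - 1] is not None:
                out[np.ix_(mask, range(index.p(i).start,
                                       index.p(i).stop))] += \
                    sign * s_pt / (FOUR_PI * sigma_m)
    return TransferMatrix(out, "Head2IP", points)


def dipsource2ip(dipoles: DipoleSet, points: SensorSet,
                 model: HeadModel) -> TransferMatrix:
    """Infinite-medium contribution v_dip(r) when the point and the dipole
    share a domain; zero otherwise."""
    if points.kind != "IP":
        raise ValueError("internal-point sensor set required")
    if dipoles.domains is None:
        dipoles = dipoles.resolve(model)
    out = np.zeros((len(points.positions), len(dipoles)))
    for dom in np.unique(dipoles.domains):
        cols = dipoles.domains == dom
        rows = points.domains == dom
        if not rows.any() or not cols.any():
            continue
        v = infinite_medium_potential(dipoles.positions[cols],
                                      dipoles.moments[cols],
                                      points.positions[rows],
                                      model.sigma(int(dom)))
        out[np.ix_(rows, cols)] = v
    return TransferMatrix(out, "Source2IP", points)
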
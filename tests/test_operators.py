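import numpy as np
import pytest

from symbem import make_icosphere
from symbem.mesh import TriangleMesh
from symbem.operators import (BasisSpace, QuadratureConfig,
                              adaptive_integrate,
                              analytic_triangle_integrals,
                              assemble_double_layer, assemble_hypersingular,
                              assemble_single_layer, mass_matrix)

TRI = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.3, 0.9, 0.0]])


def quadrature_oracle(func, tri, nsub=48):
    """Independent fine-subdivision quadrature over one triangle."""
    from symbem._kernels import gauss_rule

    qb, qw = gauss_rule(7)
    p0, p1, p2 = tri
    val = 0.0
    for i in range(nsub):
        for j in range(nsub - i):
            a = p0 + (p1 - p0) * i / nsub + (p2 - p0) * j / nsub
            b = a + (p1 - p0) / nsub
            c = a + (p2 - p0) / nsub
            cells = [np.array([a, b, c])]
            if j < nsub - i - 1:
                d = a + (p1 - p0) / nsub + (p2 - p0) / nsub
                cells.append(np.array([b, d, c]))
            for t in cells:
                area = 0.5 * np.linalg.norm(np.cross(t[1] - t[0],
                                                     t[2] - t[0]))
                pts = qb @ t
                val += area * (qw @ func(pts))
    return val


class TestAnalyticIntegrals:
    def test_far_point_matches_quadrature_to_ten_digits(self):
        point = np.array([0.4, 0.2, 1.5])
        s, d = analytic_triangle_integrals(point, TRI)
        s_q = quadrature_oracle(
            lambda p: 1.0 / (4 * np.pi * np.linalg.norm(p - point, axis=1)),
            TRI, nsub=16)
        assert s == pytest.approx(s_q, rel=1e-10)

    def test_double_layer_far_vs_quadrature(self):
        point = np.array([0.1, 0.3, 0.8])
        n = np.array([0.0, 0.0, 1.0])
        _, d = analytic_triangle_integrals(point, TRI)

        def kern(p, j):
            # dG/dn' phi_j with phi affine over TRI
            diff = point[None, :] - p
            r = np.linalg.norm(diff, axis=1)
            base = (diff @ n) / (4 * np.pi * r ** 3)
            A = np.stack([TRI[1] - TRI[0], TRI[2] - TRI[0]], axis=1)
            uv = np.linalg.lstsq(A[:2, :] if False else A, (p - TRI[0]).T,
                                 rcond=None)[0].T
            phi = np.stack([1 - uv[:, 0] - uv[:, 1], uv[:, 0], uv[:, 1]],
                           axis=1)
            return base * phi[:, j]

        for j in range(3):
            dq = quadrature_oracle(lambda p, j=j: kern(p, j), TRI, nsub=16)
            assert d[j] == pytest.approx(dq, rel=1e-8)

    def test_coplanar_outside_point_double_layer_zero(self):
        _, d = analytic_triangle_integrals([3.0, -2.0, 0.0], TRI)
        np.testing.assert_array_equal(d, 0.0)

    def test_vertex_singular_value_closed_form(self):
        # right triangle with legs a, b, observed at the right-angle
        # vertex: int 1/R dA = a * ln((b + sqrt(a^2+b^2))/a)
        a, b = 1.0, 1.0
        tri = np.array([[0.0, 0, 0], [a, 0, 0], [a, b, 0]])
        s, _ = analytic_triangle_integrals([0.0, 0.0, 0.0], tri)
        expected = a * np.log((b + np.hypot(a, b)) / a) / (4 * np.pi)
        assert np.isfinite(s)
        assert s == pytest.approx(expected, rel=1e-12)

    def test_singularity_subtraction_oracle_at_vertex(self):
        # generic triangle observed at one of its vertices: subtract the
        # closed-form right-triangle singular parts obtained by splitting
        # along the foot of the altitude from the vertex
        tri = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.5, 0.8, 0.0]])
        s, _ = analytic_triangle_integrals(tri[0], tri)
        # oracle: polar integration from the vertex: int 1/r r dr dt =
        # int rmax(t) dt, rmax from the line through the opposite edge
        e1 = tri[1] - tri[0]
        e2 = tri[2] - tri[0]
        t1 = np.arctan2(0.0, 1.0)
        ang = np.arccos(e1 @ e2 / np.linalg.norm(e1) / np.linalg.norm(e2))
        # opposite edge line: points tri[1] + s(tri[2]-tri[1])
        p, dvec = tri[1], tri[2] - tri[1]
        nline = np.array([-dvec[1], dvec[0], 0.0])
        nline /= np.linalg.norm(nline)
        dist = abs((p - tri[0]) @ nline)
        thetas = np.linspace(0.0, ang, 20001)
        # direction of e1 is theta=0
        c, s_ = np.cos(thetas), np.sin(thetas)
        dirs = np.stack([c * e1[0] / np.linalg.norm(e1)
                         - s_ * (-e1[1]) / np.linalg.norm(e1), np.zeros_like(c), np.zeros_like(c)], axis=1)
        # simpler: rotate e1^ by theta in the plane
        e1h = e1 / np.linalg.norm(e1)
        perp = np.array([-e1h[1], e1h[0], 0.0])
        if perp @ e2 < 0:
            perp = -perp
        dirs = np.outer(c, e1h) + np.outer(s_, perp)
        rmax = dist / np.abs(dirs @ nline)
        oracle = np.trapezoid(rmax, thetas) / (4 * np.pi)
        assert s == pytest.approx(oracle, rel=1e-6)


class TestAdaptiveIntegrate:
    def test_smooth_far_field_equals_base_rule(self):
        point = np.array([0.0, 0.0, 5.0])

        def f(p):
            return 1.0 / np.linalg.norm(p - point, axis=1)

        base, _ = adaptive_integrate(f, TRI, QuadratureConfig(
            adaptive=False))
        val, warn = adaptive_integrate(f, TRI, QuadratureConfig(tol=1e-6))
        assert not warn
        assert val == pytest.approx(base, rel=1e-10)

    def test_near_singular_adaptive_beats_base(self):
        point = np.array([0.3, 0.3, 0.01])
        exact, _ = analytic_triangle_integrals(point, TRI)
        exact *= 4 * np.pi

        def f(p):
            return 1.0 / np.linalg.norm(p - point, axis=1)

        base, _ = adaptive_integrate(f, TRI,
                                     QuadratureConfig(adaptive=False))
        fine, _ = adaptive_integrate(f, TRI, QuadratureConfig(tol=1e-6))
        assert abs(fine - exact) < abs(base - exact)

    def test_tolerance_monotonicity(self):
        point = np.array([0.3, 0.3, 0.02])
        exact, _ = analytic_triangle_integrals(point, TRI)
        exact *= 4 * np.pi

        def f(p):
            return 1.0 / np.linalg.norm(p - point, axis=1)

        errors = []
        for tol in (1e-1, 1e-2, 1e-4, 1e-6):
            val, _ = adaptive_integrate(f, TRI, QuadratureConfig(tol=tol))
            errors.append(abs(val - exact))
        assert all(b <= a + 1e-15 for a, b in zip(errors, errors[1:]))

    def test_max_depth_warning(self):
        point = np.array([0.3, 0.3, 1e-7])

        def f(p):
            return 1.0 / np.linalg.norm(p - point, axis=1)

        _, warn = adaptive_integrate(
            f, TRI, QuadratureConfig(tol=1e-12, max_depth=2))
        assert warn


class TestSingleLayer:
    def test_self_block_spd(self, sphere_l1, quad):
        s = assemble_single_layer(sphere_l1, sphere_l1, quad).matrix
        np.testing.assert_allclose(s, s.T, atol=0)
        ev = np.linalg.eigvalsh(s)
        assert ev.min() > 0

    def test_far_pair_point_approximation(self, quad):
        a = make_icosphere(0.01, 0)
        b = TriangleMesh(make_icosphere(0.01, 0).vertices
                         + [1.0, 0.0, 0.0],
                         make_icosphere(0.01, 0).triangles)
        s = assemble_single_layer(a, b, quad).matrix
        ca, cb = a.centroids, b.centroids
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        approx = np.outer(a.areas, b.areas) / (4 * np.pi * d)
        np.testing.assert_allclose(s, approx, rtol=1e-3)

    def test_self_triangle_integral_vs_oracle(self, quad):
        # Galerkin self-integral of one unit right triangle against a
        # singularity-subtracted oracle: the analytic inner integral K1(x)
        # is smooth, so a fine outer quadrature of it converges
        mesh = TriangleMesh(np.array([[0.0, 0, 0], [1.0, 0, 0],
                                      [0.0, 1, 0]]), [[0, 1, 2]])
        val = assemble_single_layer(mesh, mesh,
                                    QuadratureConfig(tol=1e-7)).matrix[0, 0]

        def inner(p):
            return np.array([analytic_triangle_integrals(x, np.array(
                [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]))[0] for x in p])

        oracle = quadrature_oracle(inner, np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]), nsub=24)
        assert val == pytest.approx(oracle, rel=2e-4)

    def test_coincident_distinct_meshes_rejected(self, sphere_l1, quad):
        other = TriangleMesh(sphere_l1.vertices.copy(),
                             sphere_l1.triangles[::-1].copy())
        with pytest.raises(ValueError, match="coincide"):
            assemble_single_layer(sphere_l1, other, quad)


class TestDoubleLayer:
    def test_self_row_sums_half_area(self, sphere_l1, quad):
        d, _ = assemble_double_layer(sphere_l1, sphere_l1, quad)
        rows = d.matrix.sum(axis=1)
        # accuracy is set by the quadrature tolerance, not machine epsilon
        np.testing.assert_allclose(rows, -sphere_l1.areas / 2.0,
                                   rtol=1e-6)

    def test_interior_point_constant_minus_one(self, sphere_l1):
        from symbem._kernels import point_sd, triangle_precompute

        pack = triangle_precompute(sphere_l1)
        pts = np.array([[0.0, 0.0, 0.0], [0.02, 0.01, -0.03],
                        [0.2, 0.0, 0.0], [0.0, 0.5, 0.0]])
        _, dmat = point_sd(pts, pack[0], pack[1], pack[2], pack[3],
                           pack[4], pack[5],
                           np.ascontiguousarray(sphere_l1.triangles),
                           sphere_l1.n_vertices)
        totals = dmat.sum(axis=1) / (4 * np.pi)
        np.testing.assert_allclose(totals[:2], -1.0, rtol=1e-12)
        np.testing.assert_allclose(totals[2:], 0.0, atol=1e-12)

    def test_adjoint_is_transpose(self, sphere_l1, quad):
        d, dstar = assemble_double_layer(sphere_l1, sphere_l1, quad)
        np.testing.assert_array_equal(d.matrix.T, dstar.matrix)
        assert dstar.tag == "D*"


class TestHypersingular:
    def test_annihilates_constants(self, sphere_l1, quad):
        n = assemble_hypersingular(sphere_l1, sphere_l1, quad).matrix
        rows = n @ np.ones(sphere_l1.n_vertices)
        assert np.abs(rows).max() < 1e-12 * np.abs(n).max()

    def test_self_block_symmetric_psd_with_constant_kernel(self, sphere_l1,
                                                           quad):
        n = assemble_hypersingular(sphere_l1, sphere_l1, quad).matrix
        np.testing.assert_allclose(n, n.T, atol=0)
        ev = np.linalg.eigvalsh(n)
        assert ev[0] > -1e-12 * ev[-1]   # PSD
        assert ev[1] > 1e-6 * ev[-1]     # exactly one near-zero eigenvalue

    def test_entry_vs_dense_curl_quadrature(self, quad):
        # 2-triangle open pair: dense quadrature of the curl weak form
        from symbem._kernels import gauss_rule
        from symbem.operators import p1_curl_map

        mesh_a = TriangleMesh(np.array([[0.0, 0, 0], [1.0, 0, 0],
                                        [0.0, 1, 0]]), [[0, 1, 2]])
        mesh_b = TriangleMesh(np.array([[0.0, 0, 2.0], [1.0, 0, 2.0],
                                        [0.0, 1, 2.5]]), [[0, 1, 2]])
        n = assemble_hypersingular(mesh_a, mesh_b, quad).matrix
        qa = [np.asarray(q.todense()) for q in p1_curl_map(mesh_a)]
        qb = [np.asarray(q.todense()) for q in p1_curl_map(mesh_b)]
        # dense double quadrature of int int G qa.qb
        qbq, qwq = gauss_rule(7)
        pa = qbq @ mesh_a.vertices[mesh_a.triangles[0]]
        pb = qbq @ mesh_b.vertices[mesh_b.triangles[0]]
        G = 1.0 / (4 * np.pi * np.linalg.norm(
            pa[:, None, :] - pb[None, :, :], axis=2))
        ss_q = mesh_a.areas[0] * mesh_b.areas[0] * (qwq @ G @ qwq)
        expected = sum(np.outer(qa[c][:, 0], qb[c][:, 0]) * ss_q
                       for c in range(3))
        np.testing.assert_allclose(n, expected, rtol=1e-6)

    def test_sign_vs_normal_derivative_kernel(self):
        # frozen orientation check: on disjoint closed surfaces the curl
        # form equals MINUS the Galerkin form of the dn dn' kernel
        from symbem._kernels import gauss_rule

        mA = make_icosphere(0.05, 0)
        mB0 = make_icosphere(0.04, 0)
        mB = TriangleMesh(mB0.vertices + np.array([0.3, 0.0, 0.0]),
                          mB0.triangles)
        N = assemble_hypersingular(mA, mB, QuadratureConfig()).matrix
        qb, qw = gauss_rule(7)

        def qpts(mesh):
            p0, p1, p2 = mesh.corners
            corn = np.stack([p0, p1, p2], axis=1)
            return qb[None, :, :] @ corn

        ptsA, ptsB = qpts(mA), qpts(mB)
        nA, nB = mA.face_normals, mB.face_normals
        Ndir = np.zeros((mA.n_vertices, mB.n_vertices))
        for ta in range(mA.n_triangles):
            for tb in range(mB.n_triangles):
                R = ptsA[ta][:, None, :] - ptsB[tb][None, :, :]
                r = np.linalg.norm(R, axis=2)
                ker = ((nA[ta] @ nB[tb]) / r ** 3
                       - 3 * (R @ nA[ta]) * (R @ nB[tb]) / r ** 5)
                ker /= 4 * np.pi
                w = np.outer(qw, qw) * mA.areas[ta] * mB.areas[tb]
                for a in range(3):
                    for b in range(3):
                        Ndir[mA.triangles[ta, a], mB.triangles[tb, b]] += \
                            np.sum(w * np.outer(qb[:, a], qb[:, b]) * ker)
        np.testing.assert_allclose(N, -Ndir, rtol=1e-5)


class TestMassMatrix:
    def test_p0_diagonal_areas(self, sphere_l1):
        m = mass_matrix(BasisSpace(sphere_l1, "P0"),
                        BasisSpace(sphere_l1, "P0")).matrix
        np.testing.assert_allclose(m, np.diag(sphere_l1.areas))

    def test_p1_row_sums_vertex_areas(self, sphere_l1):
        m = mass_matrix(BasisSpace(sphere_l1, "P1"),
                        BasisSpace(sphere_l1, "P1")).matrix
        np.testing.assert_allclose(m.sum(axis=1),
                                   sphere_l1.vertex_areas(), rtol=1e-12)

    def test_total_sum_is_area(self, sphere_l2):
        m = mass_matrix(BasisSpace(sphere_l2, "P1"),
                        BasisSpace(sphere_l2, "P1")).matrix
        assert m.sum() == pytest.approx(sphere_l2.total_area, rel=1e-12)

    def test_mixed_shapes(self, sphere_l1):
        m = mass_matrix(BasisSpace(sphere_l1, "P1"),
                        BasisSpace(sphere_l1, "P0")).matrix
        assert m.shape == (sphere_l1.n_vertices, sphere_l1.n_triangles)
        np.testing.assert_allclose(m.sum(axis=0), sphere_l1.areas,
                                   rtol=1e-12)

    def test_mismatched_meshes_rejected(self, sphere_l1, sphere_l2):
        with pytest.raises(ValueError):
            mass_matrix(BasisSpace(sphere_l1, "P0"),
                        BasisSpace(sphere_l2, "P0"))


class TestQuadratureProperties:
    def test_far_blocks_adaptive_agnostic(self, quad):
        a = make_icosphere(0.05, 1)
        b0 = make_icosphere(0.04, 1)
        b = TriangleMesh(b0.vertices + [0.5, 0.0, 0.0], b0.triangles)
        s_ad = assemble_single_layer(a, b, QuadratureConfig()).matrix
        s_na = assemble_single_layer(
            a, b, QuadratureConfig(adaptive=False)).matrix
        np.testing.assert_allclose(s_ad, s_na, rtol=1e-12)

    def test_rule_refinement_never_increases_error(self):
        # richer base rules never increase the entry error against a
        # tightly-converged reference on a fixed near pair
        a = make_icosphere(0.05, 0)
        b = TriangleMesh(a.vertices + [0.12, 0.0, 0.0], a.triangles)
        ref = assemble_single_layer(
            a, b, QuadratureConfig(tol=1e-10, far_factor=1e9)).matrix
        errors = []
        for npts in (1, 3, 7):
            s = assemble_single_layer(
                a, b, QuadratureConfig(n_points=npts,
                                       adaptive=False)).matrix
            errors.append(np.abs(s - ref).max())
        assert errors[0] >= errors[1] >= errors[2]

    def test_solid_angle_identity_all_levels(self, quad):
        # Galerkin row sums -area/2 at several refinements
        for level in (0, 1, 2):
            mesh = make_icosphere(0.1, level)
            d, _ = assemble_double_layer(mesh, mesh, quad)
            np.testing.assert_allclose(d.matrix.sum(axis=1),
                                       -mesh.areas / 2.0, rtol=1e-6)
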
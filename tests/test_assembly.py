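import numpy as np
import pytest

from symbem import HeadModel, make_icosphere
from symbem.assembly import (BlockIndexMap, assemble_dipole_source_matrix,
                             assemble_eit_source_matrix,
                             assemble_head_matrix,
                             assemble_surface_source_matrix, dipsource2ip,
                             dipsource2meg, head2eeg, head2ip, head2meg,
                             infinite_medium_potential, surfsource2meg)
from symbem.mesh import (DipoleSet, EITInjection, SurfaceSource,
                         TriangleMesh, internal_points, meg_sensors,
                         project_electrodes)
from symbem.operators import QuadratureConfig

RADII = (0.088, 0.092, 0.100)
SIGMAS = (1.0, 1.0 / 80.0, 1.0)


@pytest.fixture(scope="module")
def model_l1():
    return HeadModel(tuple(make_icosphere(r, 1) for r in RADII), SIGMAS)


@pytest.fixture(scope="module")
def head_l1(model_l1, quad):
    return assemble_head_matrix(model_l1, quad, decompose=True)


class TestHeadMatrix:
    def test_exactly_symmetric(self, head_l1):
        h, _ = head_l1
        assert np.abs(h.matrix - h.matrix.T).max() == 0.0

    def test_two_layer_symmetric(self, quad):
        model = HeadModel((make_icosphere(0.09, 1), make_icosphere(0.1, 1)),
                          (1.0, 0.5))
        h = assemble_head_matrix(model, quad)
        assert np.abs(h.matrix - h.matrix.T).max() == 0.0

    def test_decomposition_reassembly_exact(self, model_l1, head_l1, quad):
        _, dec = head_l1
        rng = np.random.default_rng(0)
        for _ in range(20):
            sig = rng.uniform(0.01, 5.0, size=3)
            direct = assemble_head_matrix(
                model_l1.with_conductivities(sig), quad,
                check=False).matrix
            np.testing.assert_array_equal(dec.assemble(sig), direct)

    def test_constants_in_undeflated_null_space(self, model_l1, head_l1):
        h, _ = head_l1
        undeflated = h.matrix - h.deflation_coefficient * np.outer(
            h.deflation_vector, h.deflation_vector)
        x = np.zeros(h.n)
        for i in range(1, model_l1.n_interfaces + 1):
            x[h.index.v(i)] = 1.0
        resid = undeflated @ x
        scale = np.abs(undeflated).max()
        assert np.abs(resid).max() < 1e-6 * scale

    def test_invalid_nesting_rejected(self, quad):
        model = HeadModel((make_icosphere(0.1, 1), make_icosphere(0.09, 1)),
                          (1.0, 1.0))
        with pytest.raises(ValueError, match="nested"):
            assemble_head_matrix(model, quad)

    def test_block_index_map(self, model_l1):
        idx = BlockIndexMap.for_model(model_l1)
        nv = [s.n_vertices for s in model_l1.interfaces]
        nt = [s.n_triangles for s in model_l1.interfaces]
        assert idx.total == sum(nv) + sum(nt[:-1])
        assert idx.v(1) == slice(0, nv[0])
        with pytest.raises(IndexError):
            idx.p(3)  # the scalp has no normal-current block


class TestDipoleSource:
    def test_columns_linear_in_moment(self, model_l1, quad):
        d = DipoleSet([[0, 0, 0.04], [0, 0, 0.04]],
                      [[1e-8, 0, 1e-8], [2e-8, 0, 2e-8]]).resolve(model_l1)
        s = assemble_dipole_source_matrix(model_l1, d, quad).matrix
        np.testing.assert_allclose(s[:, 1], 2.0 * s[:, 0], rtol=1e-13)

    def test_locality_rows(self, model_l1, quad):
        d = DipoleSet([[0, 0, 0.04]], [[1e-8, 0, 0]]).resolve(model_l1)
        s = assemble_dipole_source_matrix(model_l1, d, quad)
        idx = s.index
        # dipole in domain 1: only interface-1 rows may be nonzero
        assert np.abs(s.matrix[idx.v(1)]).max() > 0
        assert np.abs(s.matrix[idx.v(2)]).max() == 0.0
        assert np.abs(s.matrix[idx.v(3)]).max() == 0.0
        assert np.abs(s.matrix[idx.p(2)]).max() == 0.0

    def test_middle_domain_dipole_rows(self, model_l1, quad):
        d = DipoleSet([[0, 0, 0.0905]], [[1e-8, 0, 0]]).resolve(model_l1)
        assert d.domains[0] == 2
        s = assemble_dipole_source_matrix(model_l1, d, quad)
        idx = s.index
        assert np.abs(s.matrix[idx.v(1)]).max() > 0
        assert np.abs(s.matrix[idx.v(2)]).max() > 0
        assert np.abs(s.matrix[idx.v(3)]).max() == 0.0


class TestSurfaceSource:
    def test_zero_intensities_zero_matrix(self, model_l1, quad):
        smesh = make_icosphere(0.02, 0)
        src = SurfaceSource(smesh, np.zeros(smesh.n_vertices))
        s = assemble_surface_source_matrix(model_l1, src, quad)
        assert s.matrix.shape[1] == smesh.n_vertices
        # columns are per unit basis intensity; combination with J = 0
        assert np.abs(s.matrix @ src.intensities).max() == 0.0

    def test_combination_scales_linearly(self, model_l1, quad):
        smesh = make_icosphere(0.02, 0)
        src = assemble_surface_source_matrix(
            model_l1, SurfaceSource(smesh, np.ones(smesh.n_vertices)),
            quad)
        j = np.random.default_rng(1).standard_normal(smesh.n_vertices)
        np.testing.assert_allclose(src.matrix @ (3.0 * j),
                                   3.0 * (src.matrix @ j), rtol=1e-13)

    def test_single_triangle_vs_merged_dipoles(self, model_l1, quad):
        # a one-triangle source with equal intensities is a uniform dipole
        # layer: compare its RHS with a quadrature sum of point dipoles
        tri = np.array([[0.0, 0.0, 0.02], [0.01, 0.0, 0.02],
                        [0.0, 0.01, 0.025]])
        smesh = TriangleMesh(tri, [[0, 1, 2]])
        src = assemble_surface_source_matrix(
            model_l1, SurfaceSource(smesh, np.ones(3)), quad)
        combined = src.matrix @ np.ones(3)

        from symbem._kernels import gauss_rule

        qb, qw = gauss_rule(7)
        pts = qb @ tri
        n = smesh.face_normals[0]
        area = smesh.areas[0]
        moments = np.outer(qw * area, n)
        d = DipoleSet(pts, moments).resolve(model_l1)
        sdip = assemble_dipole_source_matrix(model_l1, d, quad)
        merged = sdip.matrix.sum(axis=1)
        ref = np.abs(combined).max()
        np.testing.assert_allclose(combined, merged, atol=2e-3 * ref)

    def test_crossing_source_rejected(self, model_l1, quad):
        smesh = make_icosphere(0.09, 0)  # crosses the inner interface
        with pytest.raises(ValueError, match="crosses|outside"):
            assemble_surface_source_matrix(
                model_l1, SurfaceSource(smesh, np.ones(smesh.n_vertices)),
                quad)


class TestHead2EEG:
    def test_vertex_electrode_single_one(self, model_l1):
        scalp = model_l1.scalp
        es = project_electrodes([scalp.vertices[5]], scalp)
        t = head2eeg(model_l1, es)
        row = t.matrix[0]
        assert np.count_nonzero(row) == 1
        assert row.max() == pytest.approx(1.0)

    def test_row_sums_one(self, model_l1):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((10, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.12
        es = project_electrodes(pts, model_l1.scalp)
        t = head2eeg(model_l1, es)
        np.testing.assert_allclose(t.matrix.sum(axis=1), 1.0, rtol=1e-12)
        assert (t.matrix >= -1e-12).all()  # convex combinations

    def test_centroid_thirds(self, model_l1):
        scalp = model_l1.scalp
        es = project_electrodes([scalp.centroids[0] * 1.0001], scalp)
        t = head2eeg(model_l1, es)
        row = t.matrix[0]
        np.testing.assert_allclose(np.sort(row[row > 1e-9]), [1 / 3] * 3,
                                   rtol=1e-3)

    def test_rows_max_three_nonzeros(self, model_l1):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((20, 3)) * 0.15
        es = project_electrodes(pts, model_l1.scalp)
        t = head2eeg(model_l1, es)
        assert (np.count_nonzero(t.matrix, axis=1) <= 3).all()


class TestHead2MEG:
    def _sensors(self, n=10, seed=4):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.15
        dirs = rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return meg_sensors(pts, dirs)

    def test_constant_potential_silent(self, model_l1, quad):
        sens = self._sensors()
        t = head2meg(model_l1, sens, quad)
        idx = BlockIndexMap.for_model(model_l1)
        x = np.zeros(idx.total)
        for i in range(1, 4):
            x[idx.v(i)] = 1.0
        readings = t.matrix @ x
        # the closed-surface cancellation holds to quadrature accuracy
        scale = np.abs(t.matrix).max()
        assert np.abs(readings).max() < 5e-3 * scale

    def test_p_blocks_receive_zero(self, model_l1, quad):
        t = head2meg(model_l1, self._sensors(), quad)
        idx = BlockIndexMap.for_model(model_l1)
        assert np.abs(t.matrix[:, idx.p(1)]).max() == 0.0
        assert np.abs(t.matrix[:, idx.p(2)]).max() == 0.0

    def test_equal_conductivity_interface_contributes_zero(self, quad):
        model = HeadModel((make_icosphere(0.09, 1), make_icosphere(0.1, 1)),
                          (0.7, 0.7))
        t = head2meg(model, self._sensors(), quad)
        idx = BlockIndexMap.for_model(model)
        # inner interface: sigma jump 0 -> no contribution
        assert np.abs(t.matrix[:, idx.v(1)]).max() == 0.0
        assert np.abs(t.matrix[:, idx.v(2)]).max() > 0.0

    def test_channel_grouping_and_weights(self, model_l1, quad):
        pts = np.array([[0.15, 0, 0], [0.15, 0, 0.01], [0, 0.15, 0]])
        dirs = np.tile([0.0, 0.0, 1.0], (3, 1))
        sens = meg_sensors(pts, dirs, weights=[0.5, 0.5, 1.0],
                           channels=["a", "a", "b"])
        t = head2meg(model_l1, sens, quad)
        assert t.matrix.shape[0] == 2


class TestSource2MEG:
    def test_parallel_moment_zero_field(self):
        r0 = np.array([0.0, 0.0, 0.04])
        sensor = np.array([[0.0, 0.0, 0.12]])
        q = np.array([[0.0, 0.0, 1e-8]])  # parallel to r - r0
        d = DipoleSet([r0], q)
        for direction in np.eye(3):
            sens = meg_sensors(sensor, direction[None, :])
            t = dipsource2meg(d, sens)
            assert abs(t.matrix[0, 0]) < 1e-30

    def test_perpendicular_magnitude_closed_form(self):
        # |B| = mu0 |q| / (4 pi d^2) perpendicular to q at distance d
        q = 1e-8
        dist = 0.1
        d = DipoleSet([[0, 0, 0]], [[q, 0, 0]])
        sens = meg_sensors([[0, dist, 0]], [[0, 0, 1]])
        t = dipsource2meg(d, sens)
        expected = 4e-7 * np.pi * q / (4 * np.pi * dist ** 2)
        assert t.matrix[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_radial_reading_matches_sarvas(self):
        from symbem.sphere import meg_sphere_field

        rng = np.random.default_rng(5)
        r0 = np.array([0.01, 0.02, 0.04])
        q = np.array([1e-8, -2e-8, 1e-8])
        pts = rng.standard_normal((6, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 0.13
        rad = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        t = dipsource2meg(DipoleSet([r0], [q]), meg_sensors(pts, rad))
        oracle = meg_sphere_field(r0, q, pts, rad)
        np.testing.assert_allclose(t.matrix[:, 0], oracle, rtol=1e-10)

    def test_surface_source_vs_dipole_sum(self):
        tri = np.array([[0.0, 0.0, 0.02], [0.01, 0.0, 0.02],
                        [0.0, 0.01, 0.02]])
        smesh = TriangleMesh(tri, [[0, 1, 2]])
        sens = meg_sensors([[0.1, 0.05, 0.1]], [[1.0, 0.0, 0.0]])
        t = surfsource2meg(SurfaceSource(smesh, np.ones(3)), sens,
                           QuadratureConfig())
        from symbem._kernels import gauss_rule

        qb, qw = gauss_rule(7)
        pts = qb @ tri
        moments = np.outer(qw * smesh.areas[0], smesh.face_normals[0])
        td = dipsource2meg(DipoleSet(pts, moments), sens)
        assert t.matrix.sum() == pytest.approx(td.matrix.sum(), rel=1e-10)


class TestEITSource:
    def test_linear_in_current(self, model_l1, quad):
        scalp = model_l1.scalp
        inj1 = EITInjection.from_points(
            [[0, 0, 0.11], [0, 0, -0.11]], [[1e-3], [-1e-3]], scalp)
        inj2 = EITInjection.from_points(
            [[0, 0, 0.11], [0, 0, -0.11]], [[2e-3], [-2e-3]], scalp)
        s1 = assemble_eit_source_matrix(model_l1, inj1, quad).matrix
        s2 = assemble_eit_source_matrix(model_l1, inj2, quad).matrix
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)

    def test_zero_current_zero_column(self, model_l1, quad):
        inj = EITInjection.from_points(
            [[0, 0, 0.11], [0, 0, -0.11]], [[0.0], [0.0]],
            model_l1.scalp)
        s = assemble_eit_source_matrix(model_l1, inj, quad).matrix
        assert np.abs(s).max() == 0.0

    def test_nonzero_net_current_rejected(self, model_l1):
        with pytest.raises(ValueError, match="sum to zero"):
            EITInjection.from_points([[0, 0, 0.11], [0, 0, -0.11]],
                                     [[1e-3], [-2e-3]], model_l1.scalp)


class TestInternalPotential:
    def test_source2ip_zero_across_domains(self, model_l1):
        d = DipoleSet([[0, 0, 0.04]], [[1e-8, 0, 1e-8]]).resolve(model_l1)
        pts = internal_points([[0, 0, 0.0905], [0, 0, 0.02]], model_l1)
        t = dipsource2ip(d, pts, model_l1)
        assert t.matrix[0, 0] == 0.0       # point in domain 2, dipole in 1
        assert t.matrix[1, 0] != 0.0       # same domain

    def test_head2ip_shapes(self, model_l1, quad):
        pts = internal_points([[0, 0, 0.02], [0.05, 0, 0.05]], model_l1)
        t = head2ip(model_l1, pts, quad)
        idx = BlockIndexMap.for_model(model_l1)
        assert t.matrix.shape == (2, idx.total)

    def test_point_on_interface_rejected(self, model_l1):
        vtx = model_l1.interfaces[0].vertices[0]
        with pytest.raises(ValueError):
            internal_points([vtx], model_l1)


class TestInfiniteMediumPotential:
    def test_perpendicular_zero(self):
        v = infinite_medium_potential([[0, 0, 0]], [[1.0, 0, 0]],
                                      [[0, 0, 1.0]], sigma=1.0)
        assert v[0, 0] == 0.0

    def test_unit_value(self):
        v = infinite_medium_potential([[0, 0, 0]], [[0, 0, 1.0]],
                                      [[0, 0, 1.0]], sigma=1.0)
        assert v[0, 0] == pytest.approx(1.0 / (4 * np.pi), rel=1e-14)

    def test_inverse_square_scaling(self):
        v1 = infinite_medium_potential([[0, 0, 0]], [[0, 0, 1.0]],
                                       [[0, 0, 1.0]], sigma=1.0)
        v2 = infinite_medium_potential([[0, 0, 0]], [[0, 0, 1.0]],
                                       [[0, 0, 2.0]], sigma=1.0)
        assert v2[0, 0] == pytest.approx(v1[0, 0] / 4.0, rel=1e-13)

    def test_gradient_finite_difference(self):
        rng = np.random.default_rng(6)
        r0, q = rng.standard_normal(3), rng.standard_normal(3)
        p = r0 + np.array([0.3, -0.2, 0.5])
        v, g = infinite_medium_potential([r0], [q], [p], sigma=2.0,
                                         gradient=True)
        eps = 1e-6
        for c in range(3):
            dp = np.zeros(3)
            dp[c] = eps
            fd = (infinite_medium_potential([r0], [q], [p + dp], 2.0)
                  - infinite_medium_potential([r0], [q], [p - dp],
                                              2.0)) / (2 * eps)
            assert g[0, 0, c] == pytest.approx(fd[0, 0], rel=1e-6)

    def test_coincident_point_rejected(self):
        with pytest.raises(ValueError):
            infinite_medium_potential([[0, 0, 0]], [[1, 0, 0]],
                                      [[0, 0, 0]], 1.0)
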
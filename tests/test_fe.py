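"""Voxel hexahedral elasticity: element, mesh, solver, reactions, strains."""

import numpy as np
import pytest

from microval import fe, hexa
from microval.dvc import DisplacementGrid, GridSpec
from microval.errors import OutOfDomainError, ParameterError, SegmentationError
from microval.segmentation import BinaryVolume


def affine_grid(shape_vox, h, A=None, b=None, ns=4):
    """DisplacementGrid carrying an affine field u = A x + b over the volume."""
    A = np.zeros((3, 3)) if A is None else np.asarray(A, float)
    b = np.zeros(3) if b is None else np.asarray(b, float)
    grid = GridSpec.cover(shape_vox, ns)
    pz, py, px = [np.asarray(p) * h for p in grid.node_positions_vox()]
    Z, Y, X = np.meshgrid(pz, py, px, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    u = (pts @ A.T + b).reshape(tuple(grid.node_counts) + (3,))
    return DisplacementGrid(grid, u, h)


def random_connected_structure(rng, n=10, fill=0.5):
    """Random connected voxel structure (largest 6-connected component)."""
    from microval.segmentation import connectivity_filter

    data = (rng.random((n, n, n)) < fill).astype(np.uint8)
    data[n // 2] = 1  # guarantee a large component
    return connectivity_filter(BinaryVolume(data, 39.0))


class TestElementStiffness:
    def test_symmetry_and_rigid_modes(self):
        K = fe.element_stiffness(fe.ElasticParams(12.0, 0.3), 39.0)
        assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w) < 1e-10 * w.max()).sum() == 6
        assert (w > 1e-10 * w.max()).sum() == 18

    def test_rigid_translation_and_linearized_rotation_in_null_space(self):
        K = fe.element_stiffness(fe.ElasticParams(8.0, 0.25), 50.0)
        translation = np.tile([1.0, -2.0, 0.5], 8)
        assert np.abs(K @ translation).max() < 1e-12 * np.abs(K).max()
        corners = hexa.CORNERS * 50.0
        rotation = np.cross([1e-4, 2e-4, -1e-4], corners).ravel()
        assert np.abs(K @ rotation).max() < 1e-12 * np.abs(K).max()

    def test_linear_in_modulus(self):
        K1 = fe.element_stiffness(fe.ElasticParams(6.0, 0.3), 39.0)
        K2 = fe.element_stiffness(fe.ElasticParams(12.0, 0.3), 39.0)
        np.testing.assert_allclose(K2, 2.0 * K1, rtol=1e-13)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ParameterError):
            fe.ElasticParams(12.0, 0.5)


class TestBuildMesh:
    def test_single_voxel(self):
        data = np.zeros((3, 3, 3), np.uint8)
        data[1, 1, 1] = 1
        mesh = fe.build_mesh(BinaryVolume(data, 39.0))
        assert mesh.n_elements == 1 and mesh.n_nodes == 8

    def test_two_face_adjacent_voxels_share_four_nodes(self):
        data = np.zeros((3, 3, 3), np.uint8)
        data[1, 1, 0] = data[1, 1, 1] = 1
        mesh = fe.build_mesh(BinaryVolume(data, 39.0))
        assert mesh.n_elements == 2 and mesh.n_nodes == 12

    def test_node_count_matches_corner_set_oracle(self, rng):
        bin_vol = random_connected_structure(rng)
        mesh = fe.build_mesh(bin_vol)
        corners = set()
        for z, y, x in np.argwhere(bin_vol.data):
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        corners.add((z + dz, y + dy, x + dx))
        assert mesh.n_nodes == len(corners)
        assert mesh.n_elements == int(bin_vol.data.sum())

    def test_empty_volume_rejected(self):
        vol = BinaryVolume(np.ones((2, 2, 2), np.uint8), 39.0)
        vol.data[:] = 0
        with pytest.raises(SegmentationError):
            fe.build_mesh(vol)


def all_boundary_bc(mesh, A, b):
    """Constrain every surface node of the mesh to the affine field A x + b."""
    nodes = mesh.nodes_um
    counts = np.zeros(mesh.n_nodes, dtype=int)
    # surface nodes belong to < 8 elements; count element incidences
    for col in range(8):
        np.add.at(counts, mesh.elements[:, col], 1)
    surface = counts < 8
    ids = np.flatnonzero(surface)
    values = nodes[ids] @ np.asarray(A, float).T + np.asarray(b, float)
    zmin = nodes[:, 2].min()
    top = ids[np.abs(nodes[ids, 2] - zmin) < 1e-9]
    return fe.BCSet(ids, values, top_node_ids=top)


class TestSolve:
    def test_patch_test_affine_reproduction_on_random_structure(self, rng):
        bin_vol = random_connected_structure(rng, n=8)
        mesh = fe.build_mesh(bin_vol)
        A = np.array([[0.002, 0.001, 0.0], [0.0005, -0.003, 0.001], [0.0, 0.002, -0.01]])
        A = 0.5 * (A + A.T)
        b = np.array([5.0, -3.0, 1.0])
        params = fe.ElasticParams(12.0, 0.3)
        bc = all_boundary_bc(mesh, A, b)
        sol = fe.solve(mesh, params, bc, method="direct")
        expected = mesh.nodes_um @ A.T + b
        scale = np.abs(expected).max()
        assert np.abs(sol.u - expected).max() < 1e-8 * scale

    def test_global_equilibrium_of_reactions(self, rng):
        bin_vol = random_connected_structure(rng, n=8)
        mesh = fe.build_mesh(bin_vol)
        params = fe.ElasticParams(12.0, 0.3)
        bc = all_boundary_bc(mesh, np.diag([0.001, 0.001, -0.01]), np.zeros(3))
        sol = fe.solve(mesh, params, bc, method="direct")
        res = fe.reaction_forces(mesh, params, bc, sol)
        scale = np.abs(res.reactions).sum()
        assert np.abs(res.equilibrium_residual).max() < 1e-8 * scale

    def test_iterative_matches_dense_direct_oracle(self, rng):
        data = np.zeros((5, 5, 5), np.uint8)
        data[1:4, 1:4, 1:4] = 1  # 27 elements
        mesh = fe.build_mesh(BinaryVolume(data, 39.0))
        params = fe.ElasticParams(12.0, 0.3)
        bc = all_boundary_bc(mesh, np.diag([0.002, -0.001, -0.008]), np.array([1.0, 0, 0]))
        sol_cg = fe.solve(mesh, params, bc, method="cg", tolerance=1e-12)
        # dense oracle: assemble K densely, eliminate, numpy.linalg.solve
        K = fe.assemble_stiffness(mesh, params).toarray()
        fixed = np.zeros(mesh.n_nodes * 3, bool)
        fdofs = (bc.node_ids[:, None] * 3 + np.arange(3)).ravel()
        fixed[fdofs] = True
        u = np.zeros(mesh.n_nodes * 3)
        u[fdofs] = bc.values.ravel()
        rhs = -(K[:, fdofs] @ bc.values.ravel())[~fixed]
        u[~fixed] = np.linalg.solve(K[np.ix_(~fixed, ~fixed)], rhs)
        oracle = u.reshape(-1, 3)
        assert np.abs(sol_cg.u - oracle).max() < 1e-8 * np.abs(oracle).max()

    def test_rigid_translation_gives_zero_strain_and_zero_reactions(self, rng):
        bin_vol = random_connected_structure(rng, n=6)
        mesh = fe.build_mesh(bin_vol)
        params = fe.ElasticParams(12.0, 0.3)
        bc = all_boundary_bc(mesh, np.zeros((3, 3)), np.array([10.0, -5.0, 2.0]))
        sol = fe.solve(mesh, params, bc, method="direct")
        res = fe.reaction_forces(mesh, params, bc, sol)
        assert res.af < 1e-9
        strains = fe.element_strains(mesh, sol)
        assert np.abs(strains.eps6).max() < 1e-12


class TestConfinedCompression:
    def setup_method(self):
        self.mesh = fe.build_mesh(BinaryVolume(np.ones((4, 4, 4), np.uint8), 1000.0))
        nodes = self.mesh.nodes_um
        L = 4000.0
        on_boundary = np.any((nodes == 0) | (nodes == L), axis=1)
        ids = np.flatnonzero(on_boundary)
        values = np.zeros((ids.size, 3))
        values[:, 2] = -0.01 * nodes[ids, 2]
        top = ids[np.abs(nodes[ids, 2]) < 1e-9]
        self.bc = fe.BCSet(ids, values, top_node_ids=top)

    def test_closed_form_axial_force(self):
        # sigma_zz = E(1-nu)/((1+nu)(1-2nu)) * eps; AF = sigma * 16 mm^2
        params = fe.ElasticParams(1.0, 0.3)
        sol = fe.solve(self.mesh, params, self.bc, method="direct")
        res = fe.reaction_forces(self.mesh, params, self.bc, sol)
        expected = 1e9 * 0.7 / (1.3 * 0.4) * 0.01 * 16e-6  # 215.3846 N
        assert res.af == pytest.approx(expected, rel=1e-9)
        strains = fe.element_strains(self.mesh, sol)
        np.testing.assert_allclose(strains.eps6[:, 2], -0.01, atol=1e-12)
        np.testing.assert_allclose(strains.principal_ue[:, 2], -10000.0, atol=1e-6)

    def test_axial_force_scales_exactly_with_modulus(self):
        p1, p2 = fe.ElasticParams(12.0, 0.3), fe.ElasticParams(4.6, 0.3)
        af = []
        for p in (p1, p2):
            sol = fe.solve(self.mesh, p, self.bc, method="direct")
            af.append(fe.reaction_forces(self.mesh, p, self.bc, sol).af)
        assert af[1] / af[0] == pytest.approx(4.6 / 12.0, rel=1e-8)


class TestBoundaryConditions:
    def test_affine_grid_values_exact_and_interior_free(self):
        data = np.ones((6, 6, 6), np.uint8)
        mesh = fe.build_mesh(BinaryVolume(data, 39.0))
        A = np.diag([0.001, 0.002, -0.01])
        field = affine_grid((6, 6, 6), 39.0, A=A, b=[1.0, 2.0, 3.0])
        bc = fe.apply_boundary_conditions(mesh, field)
        expected = mesh.nodes_um[bc.node_ids] @ A.T + [1.0, 2.0, 3.0]
        np.testing.assert_allclose(bc.values, expected, atol=1e-9)
        # only the two axial node planes are constrained: 2 * 7 * 7 nodes
        assert bc.node_ids.size == 2 * 7 * 7
        z = mesh.nodes_um[bc.node_ids, 2]
        assert set(np.round(z, 6)) == {0.0, 6 * 39.0}

    def test_grid_not_covering_mesh_raises(self):
        data = np.ones((6, 6, 6), np.uint8)
        mesh = fe.build_mesh(BinaryVolume(data, 39.0))
        small = affine_grid((4, 4, 4), 39.0)  # covers only 4 voxels of extent
        with pytest.raises(OutOfDomainError):
            fe.apply_boundary_conditions(mesh, small)


class TestElementStrains:
    def test_uniaxial_affine_strain_field(self):
        data = np.ones((3, 3, 3), np.uint8)
        mesh = fe.build_mesh(BinaryVolume(data, 39.0))
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = -0.01 * mesh.nodes_um[:, 0]
        sol = fe.FESolution(u, 1, 0.0)
        strains = fe.element_strains(mesh, sol)
        np.testing.assert_allclose(strains.principal_ue[:, 2], -10000.0, atol=1e-9)
        np.testing.assert_allclose(strains.principal_ue[:, 0], 0.0, atol=1e-9)

    def test_small_rotation_strain_is_second_order(self):
        data = np.ones((3, 3, 3), np.uint8)
        mesh = fe.build_mesh(BinaryVolume(data, 39.0))
        theta = 1e-4
        R_minus_I = np.array([[0, -theta, 0], [theta, 0, 0], [0, 0, 0]])
        u = mesh.nodes_um @ R_minus_I.T
        strains = fe.element_strains(mesh, fe.FESolution(u, 1, 0.0))
        assert np.abs(strains.principal_ue).max() < 1.0  # microstrain

    def test_centroid_strain_matches_numerical_derivative_oracle(self, rng):
        bin_vol = random_connected_structure(rng, n=5)
        mesh = fe.build_mesh(bin_vol)
        u = rng.normal(0, 1.0, (mesh.n_nodes, 3))
        sol = fe.FESolution(u, 1, 0.0)
        strains = fe.element_strains(mesh, sol)
        # oracle: central finite differences of the trilinear interpolant
        h = mesh.voxel_size
        e = 0
        u_e = u[mesh.elements[e]]
        center = np.array([0.5, 0.5, 0.5])
        eps = 1e-6
        grad = np.zeros((3, 3))  # grad[i, j] = d u_i / d x_j
        for j in range(3):
            tp, tm = center.copy(), center.copy()
            tp[j] += eps
            tm[j] -= eps
            up = hexa.shape_functions(tp) @ u_e
            um = hexa.shape_functions(tm) @ u_e
            grad[:, j] = (up - um) / (2 * eps * h)
        sym = 0.5 * (grad + grad.T)
        expected = np.array([sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]])
        np.testing.assert_allclose(strains.eps6[e], expected, atol=1e-6)


class TestYieldFractions:
    def _strains_from_ezz(self, ezz_values):
        n = len(ezz_values)
        eps6 = np.zeros((n, 6))
        eps6[:, 2] = ezz_values
        principal = hexa.principal_strains(eps6)
        return fe.StrainField(eps6, principal, np.zeros(n, np.uint8))

    def test_below_yield_gives_zero_fraction(self):
        ys = fe.yield_fractions(self._strains_from_ezz([-0.005] * 10))
        assert ys.compressive_fraction == 0.0

    def test_beyond_yield_gives_full_fraction(self):
        ys = fe.yield_fractions(self._strains_from_ezz([-0.01] * 10))
        assert ys.compressive_fraction == 1.0

    def test_half_and_half(self):
        ys = fe.yield_fractions(self._strains_from_ezz([-0.01] * 5 + [-0.005] * 5))
        assert ys.compressive_fraction == 0.5

    def test_invalid_criteria(self):
        with pytest.raises(ParameterError):
            fe.YieldCriteria(eps_p1y_ue=-1.0)
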
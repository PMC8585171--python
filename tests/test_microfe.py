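"""Voxel micro-FE: element formulation, solver verification against a
dense independent assembly, and mechanical invariants."""

import numpy as np
import pytest

from trabmech import (BinaryVolume, BoundaryConditions, ImageVolume,
                      MaterialField, MaterialMapping, build_mesh,
                      map_materials, solve_compression, summarize_field)
from trabmech.microfe import (NoLoadPathError, hex8_stiffness, von_mises,
                              _assemble, _solve_linear)

from conftest import dense_hex_solve


def solid_mesh(n, h=0.1):
    return build_mesh(BinaryVolume(np.ones((n, n, n), bool), h))


class TestMesh:
    def test_single_voxel(self):
        mesh = solid_mesh(1)
        assert mesh.n_elements == 1
        assert mesh.n_nodes == 8

    def test_two_voxels_share_four_nodes(self):
        m = np.zeros((1, 1, 2), dtype=bool)
        m[0, 0, :] = True
        mesh = build_mesh(BinaryVolume(m, 0.1))
        assert mesh.n_elements == 2
        assert mesh.n_nodes == 12

    @pytest.mark.parametrize("n", [2, 4])
    def test_solid_cube_counts(self, n):
        mesh = solid_mesh(n)
        assert mesh.n_elements == n ** 3
        assert mesh.n_nodes == (n + 1) ** 3

    def test_floating_fragment_dropped(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[:, :, 0:2] = True          # spanning wall
        m[3:5, 3:5, 5] = True        # floating island
        mesh = build_mesh(BinaryVolume(m, 0.1))
        assert mesh.n_elements == 8 * 8 * 2

    def test_parallel_spanning_columns_all_kept(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[:, 0:2, 0:2] = True
        m[:, 4:6, 4:6] = True
        mesh = build_mesh(BinaryVolume(m, 0.1))
        assert mesh.n_elements == 2 * 6 * 4

    def test_no_load_path_raises(self):
        # plates normal to the loading axis, separated by marrow
        m = np.zeros((10, 6, 6), dtype=bool)
        m[0:3] = True
        m[7:10] = True
        with pytest.raises(NoLoadPathError):
            build_mesh(BinaryVolume(m, 0.1))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_mesh(BinaryVolume(np.zeros((3, 3, 3), bool), 0.1))


class TestElementStiffness:
    def test_symmetric_psd_with_six_rigid_modes(self):
        K = hex8_stiffness(0.25, 150.0, 0.3)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        scale = np.abs(w).max()
        assert np.count_nonzero(np.abs(w) < 1e-10 * scale) == 6
        assert np.all(w > -1e-10 * scale)

    def test_linear_in_modulus(self):
        np.testing.assert_allclose(hex8_stiffness(0.1, 200.0, 0.3),
                                   2 * hex8_stiffness(0.1, 100.0, 0.3),
                                   rtol=1e-12)


class TestSolve:
    def test_homogeneous_frictionless_uniaxial(self):
        """Uniaxial Hooke's law: E=100, nu=0.3, 1% compression gives a
        uniform 1 MPa axial stress field and apparent modulus 100."""
        mesh = solid_mesh(4)
        mat = MaterialField.homogeneous(mesh.n_elements, 100.0, 0.3)
        h = mesh.nodes[:, 2].max()
        bc = BoundaryConditions.from_mesh(mesh, uz=-0.01 * h,
                                          mode="frictionless")
        sol = solve_compression(mesh, mat, bc)
        np.testing.assert_allclose(sol.stress[:, 2], -1.0, atol=1e-9)
        np.testing.assert_allclose(sol.stress[:, [0, 1, 3, 4, 5]], 0.0,
                                   atol=1e-9)
        np.testing.assert_allclose(sol.mises, 1.0, atol=1e-9)
        assert sol.apparent_modulus == pytest.approx(100.0, rel=1e-8)

    def test_von_mises_of_pure_uniaxial_state(self):
        assert von_mises(np.array([0.0, 0.0, -1.0, 0, 0, 0])) == pytest.approx(1.0)

    def test_patch_affine_displacement_gives_uniform_strain(self):
        """Patch test: prescribing an affine displacement on every
        boundary node reproduces the exact constant strain inside."""
        mesh = solid_mesh(3)
        mat = MaterialField.homogeneous(mesh.n_elements, 80.0, 0.25)
        A = np.array([[0.001, 0.0004, 0.0], [0.0004, -0.0007, 0.0002],
                      [0.0, 0.0002, -0.002]])
        xyz = mesh.nodes
        on_surf = np.any((xyz <= xyz.min(axis=0) + 1e-12)
                         | (xyz >= xyz.max(axis=0) - 1e-12), axis=1)
        surf_nodes = np.flatnonzero(on_surf)
        u_pre = xyz[surf_nodes] @ A.T
        dofs = np.concatenate([surf_nodes * 3 + c for c in range(3)])
        vals = np.concatenate([u_pre[:, c] for c in range(3)])
        K = _assemble(mesh, mat.modulus, mat.poisson_ratio)
        u = _solve_linear(K, dofs, vals, 1e-12)
        from trabmech.microfe import _recover_fields
        strain, _ = _recover_fields(mesh, mat, u)
        expect = [A[0, 0], A[1, 1], A[2, 2],
                  2 * A[0, 1], 2 * A[1, 2], 2 * A[0, 2]]
        np.testing.assert_allclose(strain, np.broadcast_to(expect, strain.shape),
                                   atol=1e-12)

    def test_dense_oracle_heterogeneous_2x2x2(self):
        """Sparse solve agrees with an independently assembled dense
        system (3x3x3 quadrature, numpy solve) to 1e-10 relative."""
        mesh = solid_mesh(2, h=0.05)
        rng = np.random.default_rng(1)
        moduli = rng.uniform(50.0, 500.0, mesh.n_elements)
        mat = MaterialField(np.ones(mesh.n_elements), moduli, 0.3)
        bc = BoundaryConditions.from_mesh(mesh, uz=-0.002)
        sol = solve_compression(mesh, mat, bc)
        dofs, vals = bc.prescribed_dofs(mesh)
        u_ref = dense_hex_solve(mesh, moduli, 0.3, dofs, vals)
        scale = np.abs(u_ref).max()
        np.testing.assert_allclose(sol.displacements.ravel(), u_ref,
                                   atol=1e-10 * scale)

    def test_equilibrium_of_face_reactions(self):
        mesh = solid_mesh(5)
        rng = np.random.default_rng(2)
        mat = MaterialField(np.ones(mesh.n_elements),
                            rng.uniform(20, 200, mesh.n_elements), 0.3)
        bc = BoundaryConditions.from_mesh(mesh, uz=-0.004)
        sol = solve_compression(mesh, mat, bc)
        resid = abs(sol.reaction_force + sol.fixed_reaction)
        assert resid < 1e-8 * abs(sol.reaction_force)

    def test_linearity_in_prescribed_displacement(self):
        mesh = solid_mesh(3)
        mat = MaterialField.homogeneous(mesh.n_elements, 120.0)
        sol1 = solve_compression(mesh, mat,
                                 BoundaryConditions.from_mesh(mesh, -0.001))
        sol2 = solve_compression(mesh, mat,
                                 BoundaryConditions.from_mesh(mesh, -0.002))
        np.testing.assert_allclose(2 * sol1.displacements, sol2.displacements,
                                   atol=1e-12)
        np.testing.assert_allclose(2 * sol1.stress, sol2.stress, atol=1e-9)
        assert sol2.reaction_force == pytest.approx(2 * sol1.reaction_force)

    def test_removing_elements_never_stiffens(self):
        base = np.ones((6, 6, 6), dtype=bool)
        apparent = []
        for carve in (0, 1, 2):
            m = base.copy()
            if carve >= 1:
                m[2:4, 2:4, 2:4] = False
            if carve >= 2:
                m[:, 4, 1] = False
            mask = BinaryVolume(m, 0.1)
            mesh = build_mesh(mask)
            mat = MaterialField.homogeneous(mesh.n_elements, 100.0)
            bc = BoundaryConditions.from_mesh(mesh, uz=-0.003)
            apparent.append(solve_compression(mesh, mat, bc).apparent_modulus)
        assert apparent[0] >= apparent[1] >= apparent[2]

    def test_plastic_flag_softens_response(self):
        mesh = solid_mesh(3)
        mat = MaterialField.homogeneous(mesh.n_elements, 100.0)
        h = mesh.nodes[:, 2].max()
        bc = BoundaryConditions.from_mesh(mesh, uz=-0.02 * h)  # past yield
        lin = solve_compression(mesh, mat, bc)
        pla = solve_compression(mesh, mat, bc, plastic=True)
        assert abs(pla.reaction_force) < abs(lin.reaction_force)
        bc_el = BoundaryConditions.from_mesh(mesh, uz=-0.002 * h)
        lin_el = solve_compression(mesh, mat, bc_el)
        pla_el = solve_compression(mesh, mat, bc_el, plastic=True)
        assert pla_el.reaction_force == pytest.approx(lin_el.reaction_force,
                                                      rel=1e-6)


class TestMaterials:
    def test_mapping_constants(self):
        mapping = MaterialMapping()
        assert mapping.density(1.0) == pytest.approx(0.00097, abs=1e-15)
        assert mapping.modulus(1.0) == pytest.approx(19.04, abs=1e-12)
        assert mapping.poisson_ratio == 0.3

    def test_map_materials_per_element(self):
        vox = np.full((2, 2, 2), 2000.0)
        vox[0, 0, 0] = 1000.0
        vol = ImageVolume(vox, 0.1)
        mesh = build_mesh(BinaryVolume(np.ones((2, 2, 2), bool), 0.1))
        mat = map_materials(vol, mesh)
        k = int(np.flatnonzero((mesh.element_voxels == 0).all(axis=1))[0])
        assert mat.density[k] == pytest.approx(0.97)
        assert mat.modulus[k] == pytest.approx(19.04 * 0.97 ** 1.64)

    def test_negative_gray_values_clamped_with_warning(self):
        vox = np.full((2, 2, 2), -100.0)
        vol = ImageVolume(vox, 0.1)
        mesh = build_mesh(BinaryVolume(np.ones((2, 2, 2), bool), 0.1))
        with pytest.warns(UserWarning):
            mat = map_materials(vol, mesh)
        assert np.all(mat.density == 0.0)
        assert np.all(mat.modulus == 0.0)


class TestSummaries:
    def _fake_solution(self, mises):
        mesh = solid_mesh(1)
        n = len(mises)
        z6 = np.zeros((n, 6))
        z3 = np.zeros((n, 3))
        from trabmech import FESolution
        return FESolution(mesh=mesh, displacements=np.zeros((8, 3)),
                          strain=z6, stress=z6, mises=np.asarray(mises, float),
                          principal_stress=z3, principal_strain=z3,
                          reaction_force=0.0, fixed_reaction=0.0,
                          apparent_modulus=0.0)

    def test_uniform_field_any_quantile(self):
        s = summarize_field(self._fake_solution([3.0] * 10), quantile=0.5)
        assert s["mises_subset"]["min"] == s["mises_subset"]["max"] == 3.0
        assert s["mises_subset"]["mean"] == 3.0

    def test_lower_quartile_subset(self):
        s = summarize_field(self._fake_solution([1.0, 2.0, 3.0, 4.0]),
                            quantile=0.75)
        assert s["mises_subset"]["n"] == 3
        assert s["mises_subset"]["mean"] == pytest.approx(2.0)
        assert s["mises_subset"]["max"] == 3.0

    def test_random_field_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.exponential(5.0, 200)
        q = 0.75
        s = summarize_field(self._fake_solution(vals), quantile=q)
        srt = np.sort(vals)
        sub = srt[srt <= np.quantile(vals, q)]
        assert s["mises_subset"]["mean"] == pytest.approx(sub.mean())
        assert s["mises_subset"]["min"] == pytest.approx(sub[0])
        assert s["mises_subset"]["max"] == pytest.approx(sub[-1])
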
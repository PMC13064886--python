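"""Finite-element reference solver: assembly, eigensolve, dataset, matching."""

import numpy as np
import pytest

from vfpinn.fem import (
    MaterialGrid,
    MeshError,
    ModalDataset,
    assemble_km,
    brick_mass,
    brick_stiffness,
    build_mesh,
    cross_config_cosine_stats,
    fixed_dof_indices,
    generate_dataset,
    match_modes,
    modal_frequencies,
    solve_modes,
    surface_dof_indices,
)
from vfpinn.geometry import GeometrySpec
from vfpinn.materials import isotropic_stiffness, voigt_to_full


class TestMesh:
    def test_node_and_element_counts_match_closed_form(self, geom):
        mesh = build_mesh(geom, (6, 4, 6))
        nx, ny, nz = mesh.shape
        assert (nx, ny, nz) == (6, 4, 6)
        assert mesh.n_nodes == (nx + 1) * (ny + 1) * (nz + 1)
        assert len(mesh.elems) == nx * ny * nz
        # interface plane coincides with a mesh plane
        assert geom.cover_depth in mesh.xs

    def test_too_coarse_resolution_rejected(self, geom):
        with pytest.raises(MeshError):
            build_mesh(geom, (2, 2, 2))

    def test_layer_tags_consistent_with_element_centroids(self, geom):
        mesh = build_mesh(geom, (6, 4, 6))
        cent = mesh.nodes[mesh.elems].mean(axis=1)
        expect = np.where(cent[:, 0] < geom.cover_depth, "cover", "body")
        np.testing.assert_array_equal(mesh.elem_layers, expect)

    def test_refinement_preserves_fixed_node_classification(self, geom):
        """Every fixed-face node coordinate of the coarse mesh must appear as
        a fixed-face node of the refined mesh (set inclusion)."""
        coarse = build_mesh(geom, (6, 4, 6))
        fine = build_mesh(geom, (12, 8, 12))
        for face in ("lateral", "anterior", "posterior"):
            c = {tuple(np.round(p, 12)) for p in coarse.nodes[coarse.face_nodes[face]]}
            f = {tuple(np.round(p, 12)) for p in fine.nodes[fine.face_nodes[face]]}
            assert c <= f


class TestAssembly:
    def test_rigid_translation_in_stiffness_null_space(self, medium_reference):
        K = medium_reference["K"]
        n = K.shape[0] // 3
        for c in range(3):
            v = np.zeros(3 * n)
            v[c::3] = 1.0
            assert np.abs(K @ v).max() < 1e-6 * np.abs(K.data).max()

    def test_mass_conserves_total_mass(self, medium_reference, geom, t3_material):
        M = medium_reference["M"]
        n = M.shape[0] // 3
        v = np.zeros(3 * n)
        v[0::3] = 1.0
        assert v @ (M @ v) == pytest.approx(
            t3_material.density * geom.volume, rel=1e-10
        )

    def test_single_element_stiffness_matches_brute_force(self):
        """Vectorised B-matrix assembly against a direct index-summation
        oracle K[3a+i,3b+k] = sum_g w |J| C_ijkl dN_a/dx_j dN_b/dx_l."""
        hx, hy, hz = 0.013, 0.007, 0.004
        C = isotropic_stiffness(2.5e3, 0.3)
        Cf = voigt_to_full(C)
        K = brick_stiffness(hx, hy, hz, C)

        gp = np.array([-1, 1]) / np.sqrt(3.0)
        corners = np.array(
            [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
             [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float
        )
        scale = np.array([2 / hx, 2 / hy, 2 / hz])
        K_ref = np.zeros((24, 24))
        detJ = hx * hy * hz / 8.0
        for gx in gp:
            for gy in gp:
                for gz in gp:
                    xi = np.array([gx, gy, gz])
                    dN = np.empty((8, 3))
                    for a in range(8):
                        s = corners[a]
                        dN[a, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) * scale[0]
                        dN[a, 1] = 0.125 * (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2]) * scale[1]
                        dN[a, 2] = 0.125 * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2] * scale[2]
                    for a in range(8):
                        for b in range(8):
                            for i in range(3):
                                for k in range(3):
                                    val = 0.0
                                    for j in range(3):
                                        for l in range(3):
                                            val += Cf[i, j, k, l] * dN[a, j] * dN[b, l]
                                    K_ref[3 * a + i, 3 * b + k] += detJ * val
        np.testing.assert_allclose(K, K_ref, rtol=1e-10, atol=1e-10)

    def test_element_mass_total(self):
        Me = brick_mass(0.01, 0.02, 0.03, 1030.0)
        v = np.zeros(24)
        v[0::3] = 1.0
        assert v @ Me @ v == pytest.approx(1030.0 * 0.01 * 0.02 * 0.03, rel=1e-12)


class TestEigensolve:
    def test_longitudinal_bar_frequency_quarter_wave(self):
        """Fixed-free rod constrained to axial motion: f1 -> c/(4L) with
        c = sqrt(E/rho) (closed-form oracle, within 1% at a converged mesh)."""
        E, rho, Lbar = 5e3, 1200.0, 0.1
        geom = GeometrySpec(thickness=0.004, body_depth=0.08, cover_depth=0.02,
                            length=0.004)
        mesh = build_mesh(geom, (40, 1, 1))
        C = isotropic_stiffness(E, 0.0)
        K, M = assemble_km(mesh, C, C, rho)
        fixed = set(fixed_dof_indices(mesh, faces=("medial",)).tolist())
        # constrain transverse motion everywhere -> pure axial dynamics
        for n in range(mesh.n_nodes):
            fixed.update((3 * n + 1, 3 * n + 2))
        lams, _ = solve_modes(K, M, np.array(sorted(fixed)), 1)
        f1 = np.sqrt(lams[0]) / (2 * np.pi)
        f_exact = np.sqrt(E / rho) / (4 * Lbar)
        assert f1 == pytest.approx(f_exact, rel=0.01)

    def test_stiffness_times_four_doubles_frequencies(self, geom, t3_material):
        f1 = modal_frequencies(t3_material, geom, (6, 4, 6), n_modes=3)
        quad = type(t3_material)(
            Et=4 * t3_material.Et,
            gap_body=4 * t3_material.gap_body,
            gap_cover=4 * t3_material.gap_cover,
        )
        f2 = modal_frequencies(quad, geom, (6, 4, 6), n_modes=3)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-9)

    def test_density_scaling_inverse_sqrt(self, geom, t3_material):
        f1 = modal_frequencies(t3_material, geom, (6, 4, 6), n_modes=2)
        heavy = type(t3_material)(
            Et=t3_material.Et,
            gap_body=t3_material.gap_body,
            gap_cover=t3_material.gap_cover,
            density=4.0 * t3_material.density,
        )
        f2 = modal_frequencies(heavy, geom, (6, 4, 6), n_modes=2)
        np.testing.assert_allclose(f2, f1 / 2.0, rtol=1e-9)

    def test_rayleigh_quotient_identity_of_eigenpairs(self, medium_reference):
        K, M = medium_reference["K"], medium_reference["M"]
        for lam, mode in zip(medium_reference["lams"], medium_reference["modes"]):
            rq = (mode @ (K @ mode)) / (mode @ (M @ mode))
            assert rq == pytest.approx(lam, rel=1e-8)

    def test_modes_unit_norm_sign_fixed_zero_on_fixed_faces(self, medium_reference):
        mesh = medium_reference["mesh"]
        fixed = fixed_dof_indices(mesh)
        for mode in medium_reference["modes"]:
            assert np.linalg.norm(mode) == pytest.approx(1.0, rel=1e-12)
            assert mode[np.argmax(np.abs(mode))] > 0
            assert np.abs(mode[fixed]).max() == 0.0

    def test_mesh_convergence_monotone(self, geom, t3_material):
        """Frequencies decrease (or change < 0.5%) as the mesh is refined."""
        fa = modal_frequencies(t3_material, geom, (6, 4, 6), 2)
        fb = modal_frequencies(t3_material, geom, (12, 8, 12), 2)
        assert np.all((fb < fa) | (np.abs(fb - fa) / fa < 0.005))


class TestDataset:
    def test_degenerate_grid_yields_single_train_configuration(self, geom):
        grid = MaterialGrid(et=(2e3,), gap_body=(20e3,), gap_cover=(10e3,))
        ds = generate_dataset(grid, geom, (4, 3, 4), n_modes=2, split_seed=0)
        assert ds.n_configs == 1
        assert list(ds.split) == ["train"]

    def test_frequencies_ascending_per_configuration(self, geom):
        grid = MaterialGrid(et=(2e3,), gap_body=(10e3, 40e3), gap_cover=(10e3,))
        ds = generate_dataset(grid, geom, (4, 3, 4), n_modes=4, split_seed=1)
        assert np.all(np.diff(ds.frequencies_hz, axis=1) > 0)
        assert np.all(ds.frequencies_hz > 0)

    def test_npz_roundtrip(self, coarse_dataset, tmp_path):
        path = tmp_path / "ds.npz"
        coarse_dataset.save_npz(path)
        back = ModalDataset.load_npz(path)
        np.testing.assert_allclose(back.frequencies_hz, coarse_dataset.frequencies_hz)
        np.testing.assert_allclose(back.modes, coarse_dataset.modes)
        np.testing.assert_array_equal(back.split, coarse_dataset.split)
        assert back.configs[3].gap_body == coarse_dataset.configs[3].gap_body
        assert back.matched_to == 0


class TestModeMatching:
    def test_anchor_matched_to_itself_is_identity(self, coarse_dataset):
        ds, tables = match_modes(coarse_dataset, anchor_idx=0)
        np.testing.assert_allclose(
            ds.frequencies_hz[0], coarse_dataset.frequencies_hz[0]
        )
        np.testing.assert_allclose(np.diag(tables[0]), 1.0, atol=1e-10)

    def test_constructed_swap_recovered(self, coarse_dataset):
        """Swapping modes 2 and 3 of one configuration by hand must be undone
        by the MAC matching."""
        ds = ModalDataset(
            mesh=coarse_dataset.mesh,
            configs=list(coarse_dataset.configs),
            frequencies_hz=coarse_dataset.frequencies_hz.copy(),
            modes=coarse_dataset.modes.copy(),
            split=coarse_dataset.split.copy(),
            grid=coarse_dataset.grid,
            seed=coarse_dataset.seed,
        )
        ds.modes[1, [1, 2]] = ds.modes[1, [2, 1]]
        ds.frequencies_hz[1, [1, 2]] = ds.frequencies_hz[1, [2, 1]]
        fixed, _ = match_modes(ds, anchor_idx=0)
        np.testing.assert_allclose(
            fixed.modes[1], coarse_dataset.modes[1], atol=1e-12
        )

    def test_mac_tables_within_unit_interval(self, coarse_dataset):
        _, tables = match_modes(coarse_dataset, anchor_idx=0)
        assert tables.min() >= 0.0 and tables.max() <= 1.0 + 1e-12


class TestCrossConfigCosine:
    @staticmethod
    def _synthetic_dataset(coarse_dataset, fields):
        n = len(fields)
        ds = ModalDataset(
            mesh=coarse_dataset.mesh,
            configs=list(coarse_dataset.configs)[:n],
            frequencies_hz=np.full((n, 1), 100.0),
            modes=np.stack(fields)[:, None, :],
            split=np.array(["train"] * n),
            grid=coarse_dataset.grid,
            seed=0,
        )
        return ds

    def test_identical_and_orthogonal_fields(self, coarse_dataset):
        ndof = coarse_dataset.mesh.n_dofs
        e1 = np.zeros(ndof); e1[0] = 1.0
        e2 = np.zeros(ndof); e2[3] = 1.0
        same = self._synthetic_dataset(coarse_dataset, [e1, e1])
        stats = cross_config_cosine_stats(same, 1)
        assert stats["median"] == pytest.approx(1.0)
        orth = self._synthetic_dataset(coarse_dataset, [e1, e2])
        stats = cross_config_cosine_stats(orth, 1)
        assert stats["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_three_fields_with_known_pairwise_cosines(self, coarse_dataset):
        """Pairwise cosines {1, 0, 0} -> mean 1/3 (hand-computable fixture)."""
        ndof = coarse_dataset.mesh.n_dofs
        e1 = np.zeros(ndof); e1[0] = 1.0
        e2 = np.zeros(ndof); e2[3] = 1.0
        ds = self._synthetic_dataset(coarse_dataset, [e1, e1, e2])
        stats = cross_config_cosine_stats(ds, 1)
        assert stats["mean"] == pytest.approx(1.0 / 3.0)
        assert stats["median"] == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_configurations(self, coarse_dataset):
        ds = self._synthetic_dataset(
            coarse_dataset, [np.ones(coarse_dataset.mesh.n_dofs)]
        )
        with pytest.raises(ValueError):
            cross_config_cosine_stats(ds, 1)

    def test_surface_subset_supported(self, coarse_dataset):
        dofs = surface_dof_indices(coarse_dataset.mesh)
        stats = cross_config_cosine_stats(coarse_dataset, 1, dof_subset=dofs)
        assert 0.0 <= stats["mean"] <= 1.0
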
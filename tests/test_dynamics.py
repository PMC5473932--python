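import numpy as np
import pytest

from mdrin.dynamics import (
    cross_correlation_matrix,
    eigenvector_overlap,
    fel_from_points,
    fel_projection,
    pca_modes,
    rmsd_series,
    superpose_trajectory,
)
from mdrin.synthetic import (
    SyntheticSpec,
    default_partition,
    hinge_mode_vector,
    make_anticorrelated_trajectory,
    make_hinge_trajectory,
)

from conftest import ca_trajectory, random_rigid_transform


class TestSuperposition:
    def test_identity_frame_unchanged(self, rng):
        coords = rng.normal(size=(1, 10, 3)) * 5
        traj = ca_trajectory(np.concatenate([coords, coords]))
        fitted = superpose_trajectory(traj)
        assert np.allclose(fitted.coordinates[1], fitted.coordinates[0], atol=1e-9)

    def test_random_rigid_transform_removed(self, rng):
        base = rng.normal(size=(10, 3)) * 5
        rot, shift = random_rigid_transform(rng)
        moved = rot.apply(base) + shift
        traj = ca_trajectory(np.stack([base, moved]))
        fitted = superpose_trajectory(traj)
        rmsd = np.sqrt(np.mean(np.sum(
            (fitted.coordinates[1] - fitted.coordinates[0]) ** 2, axis=-1)))
        assert rmsd < 1e-6

    def test_fit_selection_ignores_displaced_domain(self, rng):
        """Displacing domain a leaves the bb' fit exact while whole-protein
        RMSD stays positive."""
        spec = SyntheticSpec(n_frames=1, jitter_sigma=0.0, seed=0)
        traj0 = make_hinge_trajectory(spec)
        part = default_partition(spec)
        coords = np.repeat(traj0.coordinates, 2, axis=0)
        a_mask = traj0.topology.atom_mask(residues=part.residues("a"))
        coords[1, a_mask] += [0.0, 5.0, 0.0]
        traj = ca_trajectory(coords, residue_indices=traj0.topology.residue_indices)
        base = part.residues("b") + part.residues("b'")
        fitted = superpose_trajectory(traj, fit_residues=base)
        bb_mask = traj.topology.atom_mask(residues=base)
        d = fitted.coordinates[1] - fitted.coordinates[0]
        assert np.sqrt(np.mean(np.sum(d[bb_mask] ** 2, -1))) < 1e-6
        assert np.sqrt(np.mean(np.sum(d**2, -1))) > 1.0

    def test_too_few_fit_atoms_rejected(self, rng):
        traj = ca_trajectory(rng.normal(size=(2, 5, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            superpose_trajectory(traj, fit_residues=[1, 2])

    def test_fitting_never_increases_rmsd(self, rng):
        coords = rng.normal(size=(6, 12, 3)) * 4
        traj = ca_trajectory(coords)
        before = rmsd_series(traj)["whole"]
        after = rmsd_series(superpose_trajectory(traj))["whole"]
        assert np.all(after <= before + 1e-12)


class TestRmsd:
    def test_self_is_zero(self, rng):
        traj = ca_trajectory(rng.normal(size=(1, 7, 3)))
        assert rmsd_series(traj)["whole"].iloc[0] == 0.0

    def test_one_of_hundred_atoms_displaced_two_angstrom(self):
        coords = np.zeros((2, 100, 3))
        coords[:, :, 0] = np.arange(100) * 10.0
        coords[1, 0, 1] += 2.0
        traj = ca_trajectory(coords)
        assert rmsd_series(traj)["whole"].iloc[1] == pytest.approx(0.2)

    def test_matches_direct_oracle(self, rng):
        coords = rng.normal(size=(3, 20, 3)) * 5
        traj = ca_trajectory(coords)
        got = rmsd_series(traj)["whole"]
        want = np.sqrt(((coords - coords[0]) ** 2).sum(-1).mean(-1))
        assert np.allclose(got, want, atol=1e-12)

    def test_empty_selection_rejected(self, rng):
        traj = ca_trajectory(rng.normal(size=(2, 5, 3)))
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, selections={"x": [99]})


class TestCrossCorrelation:
    def test_unit_diagonal_and_range(self, rng):
        traj = ca_trajectory(rng.normal(size=(50, 8, 3)))
        corr = cross_correlation_matrix(traj)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.nanmax(np.abs(corr)) <= 1.0 + 1e-12
        assert np.allclose(corr, corr.T)

    def test_exact_anticorrelation(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        coords = np.zeros((40, 2, 3))
        coords[:, 0, 0] = np.sin(t)
        coords[:, 1, 0] = -np.sin(t)
        coords[:, 1, 2] = 30.0
        corr = cross_correlation_matrix(ca_trajectory(coords))
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_independent_jitter_decorrelated(self):
        rng = np.random.default_rng(0)
        traj = ca_trajectory(rng.normal(size=(10_000, 6, 3)))
        corr = cross_correlation_matrix(traj)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_zero_variance_atom_flagged_nan(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 0, 0] = np.arange(10.0)
        corr = cross_correlation_matrix(ca_trajectory(coords))
        assert np.isnan(corr[1]).all() and np.isnan(corr[:, 1]).all()
        assert corr[0, 0] == pytest.approx(1.0)

    def test_planted_antiphase_domains_block(self):
        traj, part = make_anticorrelated_trajectory(n_frames=600, seed=3)
        corr = cross_correlation_matrix(traj)
        res_ids = traj.topology.residue_ids
        ia = np.isin(res_ids, part.residues("a"))
        iap = np.isin(res_ids, part.residues("a'"))
        assert corr[np.ix_(ia, iap)].mean() <= -0.8


class TestPca:
    def test_zero_motion_all_eigenvalues_zero(self):
        traj = ca_trajectory(np.ones((10, 5, 3)))
        model = pca_modes(traj)
        assert np.allclose(model.eigenvalues, 0.0)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        coords = rng.normal(size=(40, 6, 3)) * 3
        model = pca_modes(ca_trajectory(coords))
        x = coords.reshape(40, -1)
        total = x.var(axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_components_orthonormal(self, rng):
        model = pca_modes(ca_trajectory(rng.normal(size=(30, 5, 3))))
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_projections_centred_with_diagonal_covariance(self, rng):
        model = pca_modes(ca_trajectory(rng.normal(size=(50, 4, 3))))
        assert np.allclose(model.projections.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(model.projections, rowvar=False)
        assert np.allclose(cov, np.diag(model.eigenvalues), atol=1e-8)

    def test_planted_hinge_mode_recovered(self):
        spec = SyntheticSpec(n_frames=500, hinge_amplitude=20.0,
                             jitter_sigma=0.05, seed=21)
        traj = make_hinge_trajectory(spec)
        part = default_partition(spec)
        base = part.residues("b") + part.residues("b'")
        model = pca_modes(superpose_trajectory(traj, fit_residues=base))
        assert model.variance_fractions[0] >= 0.95
        assert abs(model.components[0] @ hinge_mode_vector(spec)) >= 0.99


class TestEigenvectorOverlap:
    def test_self_overlap_is_identity(self, rng):
        model = pca_modes(ca_trajectory(rng.normal(size=(30, 5, 3))))
        ov = eigenvector_overlap(model, model, k=4)
        assert np.allclose(ov, np.eye(4), atol=1e-10)

    def test_swapped_components_give_permutation(self, rng):
        import copy

        model = pca_modes(ca_trajectory(rng.normal(size=(30, 5, 3))))
        swapped = copy.deepcopy(model)
        swapped.components[[0, 1]] = swapped.components[[1, 0]]
        ov = eigenvector_overlap(model, swapped, k=2)
        assert np.allclose(ov, [[0, 1], [1, 0]], atol=1e-10)

    def test_half_trajectory_consistency_for_planted_mode(self):
        spec = SyntheticSpec(n_frames=800, hinge_amplitude=20.0,
                             jitter_sigma=0.05, seed=9)
        traj = make_hinge_trajectory(spec)
        half = traj.n_frames // 2
        first = ca_trajectory(traj.coordinates[:half],
                              traj.topology.residue_indices)
        second = ca_trajectory(traj.coordinates[half:],
                               traj.topology.residue_indices)
        ov = eigenvector_overlap(pca_modes(first), pca_modes(second), k=1)
        assert ov[0, 0] >= 0.9

    def test_dimension_mismatch_rejected(self, rng):
        a = pca_modes(ca_trajectory(rng.normal(size=(20, 5, 3))))
        b = pca_modes(ca_trajectory(rng.normal(size=(20, 4, 3))))
        with pytest.raises(ValueError, match="selection"):
            eigenvector_overlap(a, b, k=2)


class TestFel:
    def test_gaussian_minimum_near_sample_mean(self):
        rng = np.random.default_rng(5)
        xy = rng.normal(loc=[2.0, -1.0], scale=1.0, size=(20_000, 2))
        grid = fel_from_points(xy, grid_size=80)
        i, j = np.unravel_index(np.argmin(grid.free_energy),
                                grid.free_energy.shape)
        argmin = np.array([grid.x[i], grid.y[j]])
        assert np.linalg.norm(argmin - xy.mean(axis=0)) <= grid.bandwidth

    def test_global_minimum_is_zero(self):
        rng = np.random.default_rng(6)
        grid = fel_from_points(rng.normal(size=(2_000, 2)))
        assert grid.free_energy.min() == 0.0
        assert np.isfinite(grid.free_energy).all()

    def test_two_clusters_two_local_minima(self):
        rng = np.random.default_rng(7)
        c1 = rng.normal(loc=[0.0, 0.0], size=(5_000, 2))
        c2 = rng.normal(loc=[12.0, 0.0], size=(5_000, 2))
        grid = fel_from_points(np.vstack([c1, c2]), grid_size=120)
        minima = grid.local_minima()
        assert len(minima) == 2
        centers = sorted(minima)
        assert np.linalg.norm(np.array(centers[0]) - [0, 0]) <= grid.bandwidth
        assert np.linalg.norm(np.array(centers[1]) - [12, 0]) <= grid.bandwidth

    def test_frame_order_irrelevant(self):
        rng = np.random.default_rng(8)
        xy = rng.normal(size=(3_000, 2))
        a = fel_from_points(xy, grid_size=40)
        b = fel_from_points(xy[rng.permutation(len(xy))], grid_size=40)
        assert np.allclose(a.free_energy, b.free_energy, atol=1e-10)

    def test_zero_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError, match="bandwidth"):
            fel_from_points(rng.normal(size=(500, 2)), bandwidth=0.0)

    def test_projection_uses_requested_components(self):
        spec = SyntheticSpec(n_frames=300, jitter_sigma=0.2, seed=30)
        model = pca_modes(make_hinge_trajectory(spec))
        grid = fel_projection(model, components=(1, 3), grid_size=30)
        assert grid.components == (1, 3)
        with pytest.raises(ValueError, match="component"):
            fel_projection(model, components=(0, 1))
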
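"""Spatial ICA, beta-loading regression, z-maps, and stability."""

import numpy as np
import pytest

from sbmorph import (
    BrainMask,
    CohortConfig,
    FlatMatrix,
    align_components,
    component_stability,
    decompose,
    estimate_loadings,
    flatten_volumes,
    generate_cohort,
    zscore_component,
)

SMALL = (12, 14, 12)


def _planted_matrix(n_sources=3, n_subjects=60, noise_sd=0.0, seed=0,
                    grid=SMALL):
    cfg = CohortConfig(n_subjects=n_subjects, n_sources=n_sources,
                       noise_sd=noise_sd, grid_shape=grid, source_extent=2.0,
                       ab_positive_fraction=0.5, loading_shift=1.0,
                       seed=seed)
    volumes, table, truth = generate_cohort(cfg)
    matrix = flatten_volumes(volumes, BrainMask.full(grid))
    return matrix, truth


class TestDecompose:
    def test_recovers_planted_sources(self):
        matrix, truth = _planted_matrix(n_sources=3)
        comps = decompose(matrix, 3, seed=0)
        planted = np.stack([s.weights.ravel() for s in truth.sources])
        _, _, corr = align_components(planted, comps.maps)
        assert np.abs(corr).min() >= 0.95

    def test_single_source_limit(self):
        # mix exactly one source with the second source's loadings zeroed
        matrix, truth = _planted_matrix(n_sources=2, seed=1)
        single = FlatMatrix(
            data=np.outer(truth.loadings[:, 0],
                          truth.sources[0].weights.ravel()),
            voxel_index=matrix.voxel_index,
            grid_shape=matrix.grid_shape,
            subject_ids=matrix.subject_ids,
        )
        comps = decompose(single, 1, seed=0)
        _, _, corr = align_components(
            truth.sources[0].weights.ravel()[None, :], comps.maps
        )
        assert abs(corr[0]) >= 0.99

    def test_deterministic_for_fixed_seed(self):
        matrix, _ = _planted_matrix()
        a = decompose(matrix, 3, seed=7)
        b = decompose(matrix, 3, seed=7)
        np.testing.assert_array_equal(a.maps, b.maps)
        np.testing.assert_array_equal(a.loadings, b.loadings)

    def test_reconstruction_explains_full_variance_noise_free(self):
        matrix, _ = _planted_matrix(n_sources=4, seed=2)
        comps = decompose(matrix, 4, seed=0)
        centered = matrix.data - comps.train_mean
        resid = centered - comps.loadings @ comps.maps
        assert resid.var() / centered.var() < 0.01

    def test_recovery_degrades_with_noise(self):
        worst = []
        for noise in (0.0, 0.5, 1.0, 2.0):
            matrix, truth = _planted_matrix(noise_sd=noise, seed=3)
            comps = decompose(matrix, 3, seed=0)
            planted = np.stack([s.weights.ravel() for s in truth.sources])
            _, _, corr = align_components(planted, comps.maps)
            worst.append(np.abs(corr).min())
        assert worst[0] >= 0.95
        # non-strict monotone degradation, small numerical slack
        assert all(b <= a + 0.02 for a, b in zip(worst, worst[1:]))

    def test_k_too_large_raises(self):
        matrix, _ = _planted_matrix(n_subjects=10)
        with pytest.raises(ValueError, match="rank"):
            decompose(matrix, 10, seed=0)

    def test_constant_subject_row_rejected(self):
        matrix, _ = _planted_matrix()
        matrix.data[0] = 1.0
        with pytest.raises(ValueError, match="constant"):
            decompose(matrix, 2, seed=0)

    def test_loadings_invariant_to_subject_order(self):
        matrix, _ = _planted_matrix(seed=4)
        comps = decompose(matrix, 3, seed=0)
        perm = np.random.default_rng(0).permutation(matrix.n_subjects)
        permuted = FlatMatrix(
            data=matrix.data[perm],
            voxel_index=matrix.voxel_index,
            grid_shape=matrix.grid_shape,
            subject_ids=[matrix.subject_ids[i] for i in perm],
        )
        lo = estimate_loadings(permuted, comps)
        np.testing.assert_allclose(lo, comps.loadings[perm], atol=1e-8)

    def test_constant_image_absorbed_by_train_mean_on_refit(self):
        matrix, _ = _planted_matrix(seed=4)
        comps = decompose(matrix, 3, seed=0)
        shifted = FlatMatrix(
            data=matrix.data + 5.0,  # constant image added to everyone
            voxel_index=matrix.voxel_index,
            grid_shape=matrix.grid_shape,
            subject_ids=matrix.subject_ids,
        )
        refit = decompose(shifted, 3, seed=0)
        np.testing.assert_allclose(refit.train_mean, comps.train_mean + 5.0)
        np.testing.assert_allclose(refit.maps, comps.maps, atol=1e-10)
        np.testing.assert_allclose(refit.loadings, comps.loadings, atol=1e-10)


class TestEstimateLoadings:
    def test_noise_free_ols_identity(self):
        matrix, _ = _planted_matrix()
        comps = decompose(matrix, 3, seed=0)
        target = np.array([2.0, 0.0, 0.0])
        vol_row = comps.train_mean + target @ comps.maps
        probe = FlatMatrix(data=vol_row[None, :],
                           voxel_index=matrix.voxel_index,
                           grid_shape=matrix.grid_shape, subject_ids=["p"])
        np.testing.assert_allclose(
            estimate_loadings(probe, comps)[0], target, atol=1e-8
        )

    def test_train_mean_maps_to_zero_beta(self):
        matrix, _ = _planted_matrix()
        comps = decompose(matrix, 3, seed=0)
        probe = FlatMatrix(data=comps.train_mean[None, :],
                           voxel_index=matrix.voxel_index,
                           grid_shape=matrix.grid_shape, subject_ids=["p"])
        np.testing.assert_allclose(
            estimate_loadings(probe, comps)[0], np.zeros(3), atol=1e-8
        )

    def test_orthonormal_maps_equal_inner_products(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(50, 3)))
        maps = q.T  # 3 orthonormal rows
        x = rng.normal(size=50)
        from sbmorph.decompose import ComponentSet

        comps = ComponentSet(
            maps=maps, loadings=np.zeros((1, 3)), train_mean=np.zeros(50),
            voxel_index=np.arange(50), grid_shape=(50, 1, 1), fit_seed=0,
        )
        probe = FlatMatrix(data=x[None, :], voxel_index=np.arange(50),
                           grid_shape=(50, 1, 1), subject_ids=["p"])
        beta = estimate_loadings(probe, comps)[0]
        np.testing.assert_allclose(beta, maps @ x, atol=1e-10)

    def test_voxel_dimension_mismatch_raises(self):
        matrix, _ = _planted_matrix()
        comps = decompose(matrix, 2, seed=0)
        probe = FlatMatrix(data=np.zeros((1, 5)), voxel_index=np.arange(5),
                           grid_shape=(5, 1, 1), subject_ids=["p"])
        with pytest.raises(ValueError, match="voxel dimension"):
            estimate_loadings(probe, comps)


class TestZScore:
    def _comps(self, map_row):
        from sbmorph.decompose import ComponentSet

        n = map_row.size
        return ComponentSet(
            maps=map_row[None, :], loadings=np.zeros((1, 1)),
            train_mean=np.zeros(n), voxel_index=np.arange(n),
            grid_shape=(n, 1, 1), fit_seed=0,
        )

    def test_standardized_map_is_its_own_zmap(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=1000)
        row = (row - row.mean()) / row.std()
        zm = zscore_component(self._comps(row), 0, threshold=-np.inf)
        np.testing.assert_allclose(zm.z.ravel(), row, atol=1e-12)

    def test_surviving_voxel_count(self):
        row = np.zeros(1000)
        row[:10] = 100.0  # exactly 10 voxels far above mean + 1 SD
        zm = zscore_component(self._comps(row), 0, threshold=1.0)
        assert zm.n_surviving == 10

    def test_threshold_minus_inf_keeps_all(self):
        rng = np.random.default_rng(2)
        zm = zscore_component(self._comps(rng.normal(size=64)), 0,
                              threshold=-np.inf)
        assert zm.n_surviving == 64

    def test_constant_map_rejected(self):
        from sbmorph.decompose import ComponentSet

        with pytest.raises(ValueError):
            ComponentSet(
                maps=np.ones((1, 10)), loadings=np.zeros((1, 1)),
                train_mean=np.zeros(10), voxel_index=np.arange(10),
                grid_shape=(10, 1, 1), fit_seed=0,
            )


class TestStability:
    def test_identical_seeds_give_perfect_stability(self):
        matrix, _ = _planted_matrix()
        rep = component_stability(matrix, 3, n_runs=2, seeds=[5, 5])
        assert rep["mean_stability"] == pytest.approx(1.0)

    def test_planted_cohort_is_stable_noise_is_not(self):
        matrix, _ = _planted_matrix(seed=6)
        planted = component_stability(matrix, 3, n_runs=3, seeds=[0, 1, 2])
        assert planted["mean_stability"] >= 0.95

        rng = np.random.default_rng(0)
        noise = FlatMatrix(data=rng.normal(size=(40, 500)),
                           voxel_index=np.arange(500),
                           grid_shape=(500, 1, 1),
                           subject_ids=[str(i) for i in range(40)])
        pure = component_stability(noise, 5, n_runs=3, seeds=[0, 1, 2])
        assert pure["mean_stability"] < planted["mean_stability"] - 0.1
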
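import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ossart import (
    ImageGrid,
    ReconConfig,
    Sinogram,
    build_base_matrix,
    default_geometry,
    error_correction,
    forward_project_angle,
    make_shepp_logan,
    ossart_update,
    partition_subsets,
    reconstruct,
    rmse,
)
from ossart.geometry import ParallelBeamGeometry


class TestPartitionSubsets:
    def test_360_into_20_by_index_modulo(self):
        subsets = partition_subsets(360, 20)
        assert subsets.t == 20
        assert all(len(s) == 18 for s in subsets.subsets)
        assert subsets.subsets[0] == list(range(0, 360, 20))
        assert subsets.subsets[1] == list(range(1, 360, 20))

    def test_single_subset_is_sirt_regime(self):
        subsets = partition_subsets(7, 1)
        assert subsets.subsets == [list(range(7))]

    def test_singleton_subsets_are_sart_regime(self):
        subsets = partition_subsets(5, 5)
        assert subsets.subsets == [[0], [1], [2], [3], [4]]

    def test_rejects_more_subsets_than_projections(self):
        with pytest.raises(ValueError):
            partition_subsets(4, 5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(1, 64).flatmap(lambda q: st.tuples(st.just(q), st.integers(1, q))))
    def test_partition_is_disjoint_cover(self, qt):
        q, t = qt
        subsets = partition_subsets(q, t)
        flat = [i for s in subsets.subsets for i in s]
        assert sorted(flat) == list(range(q))
        assert all(len(s) >= 1 for s in subsets.subsets)
        assert all(i % t == l for l, s in enumerate(subsets.subsets) for i in s)


class TestErrorCorrection:
    def test_converged_rays_give_zero(self):
        p = np.array([1.0, 2.0, 3.0])
        assert np.all(error_correction(p, p, np.ones(3)) == 0.0)

    def test_direct_formula(self):
        out = error_correction(np.array([2.0]), np.array([1.0]), np.array([4.0]))
        assert out.tolist() == [0.25]

    def test_zero_row_sum_gives_zero_correction(self):
        out = error_correction(np.array([5.0]), np.array([1.0]), np.array([0.0]))
        assert out.tolist() == [0.0]

    def test_matches_scalar_loop(self, rng):
        p = rng.normal(size=16)
        fwd = rng.normal(size=16)
        rs = np.abs(rng.normal(size=16))
        rs[3] = 0.0
        out = error_correction(p, fwd, rs)
        for i in range(16):
            expected = 0.0 if rs[i] == 0 else (p[i] - fwd[i]) / rs[i]
            assert out[i] == pytest.approx(expected, rel=1e-15)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            error_correction(np.array([np.nan]), np.array([0.0]), np.array([1.0]))


def dense_sart_step(f, p, w_dense, lam):
    """Independent dense-matrix oracle for one simultaneous update at the
    base angle: f += lam * W^T((p - Wf)/rowsum) / colsum, with 0/0 -> 0."""
    row = w_dense.sum(axis=1)
    col = w_dense.sum(axis=0)
    resid = np.where(row > 0, (p - w_dense @ f) / np.where(row > 0, row, 1.0), 0.0)
    update = np.where(col > 0, (w_dense.T @ resid) / np.where(col > 0, col, 1.0), 0.0)
    return f + lam * update


class TestOssartUpdate:
    def test_consistent_data_is_fixed_point_at_base_angle(self, sl64, base64x64):
        geom = ParallelBeamGeometry(np.array([0.0]), 64, 1.0)
        sino = Sinogram(
            forward_project_angle(sl64, 0.0, base64x64)[None, :], geom
        )
        out = ossart_update(sl64, [0], sino, base64x64, 1.0)
        assert rmse(out, sl64) <= 1e-6

    def test_zero_relaxation_leaves_image_unchanged(self, pair16):
        phantom, sino = pair16
        base = build_base_matrix(sino.geometry, 16)
        out = ossart_update(phantom, [0, 1, 2], sino, base, 0.0)
        assert np.array_equal(out.values, phantom.values)

    def test_matches_dense_matrix_oracle_on_8x8(self):
        phantom = make_shepp_logan(8)
        geom = ParallelBeamGeometry(np.array([0.0]), 8, 1.0)
        base = build_base_matrix(geom, 8)
        p = forward_project_angle(phantom, 0.0, base) * 1.5  # inconsistent data
        sino = Sinogram(p[None, :], geom)
        out = ossart_update(phantom, [0], sino, base, 0.3)
        expected = dense_sart_step(
            phantom.values.ravel(), p, base.matrix.toarray(), 0.3
        )
        np.testing.assert_allclose(out.values.ravel(), expected, atol=1e-12)

    def test_empty_subset_rejected(self, pair16):
        phantom, sino = pair16
        base = build_base_matrix(sino.geometry, 16)
        with pytest.raises(ValueError):
            ossart_update(phantom, [], sino, base, 0.2)


class TestRmse:
    def test_identical_images_give_zero(self, sl64):
        assert rmse(sl64, sl64) == 0.0

    def test_unit_offset_gives_one(self):
        a = ImageGrid(np.zeros((5, 5)))
        b = ImageGrid(np.ones((5, 5)))
        assert rmse(a, b) == 1.0
        assert rmse(b, a) == 1.0

    def test_matches_scalar_loop(self, rng):
        a = rng.normal(size=(4, 4))
        b = rng.normal(size=(4, 4))
        acc = sum((a[i, j] - b[i, j]) ** 2 for i in range(4) for j in range(4))
        assert rmse(ImageGrid(a), ImageGrid(b)) == pytest.approx(
            np.sqrt(acc / 16), rel=1e-12
        )

    def test_shape_mismatch_rejected(self, sl64):
        with pytest.raises(ValueError):
            rmse(sl64, ImageGrid(np.zeros((4, 4))))


class TestReconstruct:
    def test_single_sirt_update_beats_zero_image(self, pair64):
        phantom, sino = pair64
        config = ReconConfig(lambda_relax=0.2, t_subsets=1, iterations=1)
        result = reconstruct(sino, config, ground_truth=phantom)
        zero_rmse = rmse(ImageGrid(np.zeros((64, 64))), phantom)
        assert len(result.rmse_history) == 1
        assert result.rmse_history[0] < zero_rmse

    def test_update_count_is_iterations_times_subsets(self, pair16):
        phantom, sino = pair16
        config = ReconConfig(t_subsets=20, iterations=10)
        result = reconstruct(sino, config, ground_truth=phantom)
        assert result.updates_performed == 200
        assert len(result.rmse_history) == 200

    def test_monotone_early_convergence(self, pair64):
        """RMSE after update k+T stays below RMSE after update k during the
        first iterations (noiseless data, lambda=0.2, T=20)."""
        phantom, sino = pair64
        config = ReconConfig(lambda_relax=0.2, t_subsets=20, iterations=5)
        h = reconstruct(sino, config, ground_truth=phantom).rmse_history
        t = 20
        assert all(h[k + t] <= h[k] for k in range(len(h) - t))

    def test_estimate_stays_finite_with_rays_missing_grid(self):
        # detector array twice as wide as the image: outer rays miss entirely
        phantom = make_shepp_logan(16)
        geom = ParallelBeamGeometry(np.arange(0.0, 180.0, 30.0), 32, 1.0)
        from ossart.simulate import simulate_sinogram

        sino = simulate_sinogram(phantom, geom)
        base = build_base_matrix(geom, 16)
        result = reconstruct(
            sino, ReconConfig(t_subsets=2, iterations=3), n=16, base=base
        )
        assert np.all(np.isfinite(result.image.values))

    def test_relative_change_stopping_rule(self, pair16):
        phantom, sino = pair16
        config = ReconConfig(t_subsets=4, iterations=50)
        result = reconstruct(sino, config, rel_change_tol=0.05)
        assert result.updates_performed < 50 * 4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReconConfig(lambda_relax=0.0)
        with pytest.raises(ValueError):
            ReconConfig(lambda_relax=1.5)
        with pytest.raises(ValueError):
            ReconConfig(iterations=0)
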
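import numpy as np
import pytest

from gliocam import nn
from gliocam.gradcam3d import (FeatureMapStack, SaliencyVolume, cam_combine,
                               cam_weights, class_average, compute_silhouette,
                               extract_features_and_grads, index_to_template,
                               resample_align, silhouette_mask)
from gliocam.io_formats import VolumeGrid
from gliocam.preprocessing import SurvivalLabel
from gliocam.survival_model import SurvivalCNN


class ToyCAMModel(SurvivalCNN):
    """Two-filter single-block model with the same saliency hooks as the
    full classifier.

    The conv bias is shifted positive so activations are strictly positive
    almost surely: finite differences are then taken away from the ReLU and
    max-pool kinks, where the gradient is well defined.
    """

    def __init__(self, in_channels=1, seed=0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        conv = nn.Conv3D(in_channels, 2, (3, 3, 3), rng=rng, dtype=dtype)
        conv.b += 2.0
        self.layers = [
            conv,
            nn.ReLU(),
            nn.MaxPool3D(2),
            nn.Flatten(),
            nn.Dense(2 * 3 * 3 * 3, 3, rng=rng, dtype=dtype),
        ]
        self.final_relu_index = 1
        self.config = None


def _stack(acts, grads, cls=SurvivalLabel.SHORT):
    return FeatureMapStack(activations=np.asarray(acts, float),
                           gradients=np.asarray(grads, float),
                           target_class=cls, logits=np.zeros(3))


class TestCamWeights:
    def test_all_ones_gradient(self):
        s = _stack(np.ones((2, 2, 2, 3)), np.ones((2, 2, 2, 3)))
        np.testing.assert_allclose(cam_weights(s), [1.0, 1.0, 1.0])

    def test_all_zero_gradient(self):
        s = _stack(np.ones((2, 2, 2, 2)), np.zeros((2, 2, 2, 2)))
        np.testing.assert_allclose(cam_weights(s), [0.0, 0.0])

    def test_hand_summed_mean(self):
        grads = np.array([1.0, 2.0, 3.0, 6.0]).reshape(4, 1, 1, 1)
        s = _stack(np.ones((4, 1, 1, 1)), grads)
        assert cam_weights(s)[0] == pytest.approx(3.0)  # (1+2+3+6)/4

    def test_normalizer_is_feature_map_voxel_count(self):
        s = _stack(np.ones((3, 4, 5, 2)), np.ones((3, 4, 5, 2)))
        assert s.Z == 60


class TestCamCombine:
    def test_negative_sum_clamped_to_zero(self):
        s = _stack(np.ones((2, 2, 2, 2)), np.zeros((2, 2, 2, 2)))
        out = cam_combine(np.array([1.0, -2.0]), s)
        assert np.all(out.data == 0.0)
        assert out.stage == "raw_cam"

    def test_zero_weights(self):
        s = _stack(np.random.default_rng(0).random((2, 2, 2, 2)),
                   np.zeros((2, 2, 2, 2)))
        assert np.all(cam_combine(np.zeros(2), s).data == 0.0)

    def test_hand_arithmetic(self):
        acts = np.zeros((1, 1, 1, 2))
        acts[0, 0, 0] = [3.0, 4.0]
        s = _stack(acts, np.zeros_like(acts))
        out = cam_combine(np.array([2.0, 1.0]), s)
        assert out.data[0, 0, 0] == pytest.approx(10.0)  # 2*3 + 1*4

    def test_weight_count_mismatch(self):
        s = _stack(np.ones((2, 2, 2, 2)), np.ones((2, 2, 2, 2)))
        with pytest.raises(ValueError, match="weights"):
            cam_combine(np.ones(3), s)


class TestResampleAlign:
    def _raw(self, data):
        data = np.asarray(data, float)
        return SaliencyVolume(data=data, grid=VolumeGrid(shape=data.shape),
                              stage="raw_cam")

    def test_same_grid_is_identity(self, rng):
        cam = self._raw(rng.random((4, 4, 4)))
        out = resample_align(cam, cam.grid)
        np.testing.assert_array_equal(out.data, cam.data)
        assert out.stage == "resampled"

    def test_constant_stays_constant(self):
        cam = self._raw(np.full((3, 3, 3), 2.5))
        out = resample_align(cam, VolumeGrid(shape=(7, 5, 9)))
        np.testing.assert_allclose(out.data, 2.5)

    def test_linear_ramp_midpoints(self):
        # corner-aligned upsample n -> 2n-1 lands new samples exactly halfway
        ramp = np.arange(4, dtype=float)[:, None, None] * np.ones((4, 3, 3))
        cam = self._raw(ramp)
        out = resample_align(cam, VolumeGrid(shape=(7, 3, 3)))
        np.testing.assert_allclose(out.data[:, 1, 1],
                                   [0, 0.5, 1, 1.5, 2, 2.5, 3])

    def test_requires_raw_stage(self, rng):
        vol = SaliencyVolume(data=rng.random((4, 4, 4)),
                             grid=VolumeGrid(shape=(4, 4, 4)), stage="resampled")
        with pytest.raises(ValueError, match="stage"):
            resample_align(vol, VolumeGrid(shape=(8, 8, 8)))

    def test_nonnegativity_preserved(self, rng):
        cam = self._raw(rng.random((5, 5, 5)))
        out = resample_align(cam, VolumeGrid(shape=(12, 9, 11)))
        assert (out.data >= 0).all()


class TestClassAverage:
    def _resampled(self, data, cls=SurvivalLabel.LONG):
        data = np.asarray(data, float)
        return SaliencyVolume(data=data, grid=VolumeGrid(shape=data.shape),
                              stage="resampled", target_class=cls)

    def test_single_map_is_itself(self, rng):
        m = self._resampled(rng.random((3, 3, 3)))
        out = class_average([m], SurvivalLabel.LONG)
        np.testing.assert_array_equal(out.data, m.data)

    def test_midpoint_of_two(self):
        a = self._resampled(np.zeros((2, 2, 2)))
        b = self._resampled(np.full((2, 2, 2), 2.0))
        out = class_average([a, b], SurvivalLabel.LONG)
        np.testing.assert_allclose(out.data, 1.0)

    def test_matches_per_voxel_mean_oracle(self, rng):
        maps = [self._resampled(rng.random((4, 4, 2))) for _ in range(5)]
        out = class_average(maps, SurvivalLabel.LONG)
        # brute-force oracle: accumulate voxel by voxel
        acc = np.zeros((4, 4, 2))
        for m in maps:
            acc += m.data
        np.testing.assert_allclose(out.data, acc / 5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            class_average([], SurvivalLabel.SHORT)

    def test_class_mismatch_rejected(self, rng):
        a = self._resampled(rng.random((2, 2, 2)), SurvivalLabel.SHORT)
        with pytest.raises(ValueError, match="class"):
            class_average([a], SurvivalLabel.LONG)


class TestTemplateIndexing:
    def test_window_bookkeeping(self, rng):
        data = rng.random((4, 4, 9))
        avg = SaliencyVolume(data=data, grid=VolumeGrid(shape=(4, 4, 9)),
                             stage="class_average")
        out = index_to_template(avg, VolumeGrid(shape=(4, 4, 15)), (5, 14))
        np.testing.assert_array_equal(out.data[:, :, 5], data[:, :, 0])
        np.testing.assert_array_equal(out.data[:, :, 13], data[:, :, 8])

    def test_outside_window_is_zero(self, rng):
        avg = SaliencyVolume(data=rng.random((4, 4, 5)) + 1.0,
                             grid=VolumeGrid(shape=(4, 4, 5)),
                             stage="class_average")
        out = index_to_template(avg, VolumeGrid(shape=(4, 4, 12)), (3, 8))
        assert np.all(out.data[:, :, :3] == 0)
        assert np.all(out.data[:, :, 8:] == 0)

    def test_full_window_is_identity(self, rng):
        data = rng.random((4, 4, 6))
        avg = SaliencyVolume(data=data, grid=VolumeGrid(shape=(4, 4, 6)),
                             stage="class_average")
        out = index_to_template(avg, VolumeGrid(shape=(4, 4, 6)), (0, 6))
        np.testing.assert_array_equal(out.data, data)

    def test_inconsistent_window_rejected(self, rng):
        avg = SaliencyVolume(data=rng.random((4, 4, 5)),
                             grid=VolumeGrid(shape=(4, 4, 5)),
                             stage="class_average")
        with pytest.raises(ValueError, match="window"):
            index_to_template(avg, VolumeGrid(shape=(4, 4, 12)), (3, 9))


class TestSilhouetteMask:
    def _indexed(self, data):
        return SaliencyVolume(data=np.asarray(data, float),
                              grid=VolumeGrid(shape=np.asarray(data).shape),
                              stage="template_indexed")

    def test_all_ones_identity(self, rng):
        vol = self._indexed(rng.random((3, 3, 3)))
        out = silhouette_mask(vol, np.ones((3, 3, 3)))
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.stage == "masked"

    def test_all_zeros_silhouette(self, rng):
        vol = self._indexed(rng.random((3, 3, 3)))
        assert np.all(silhouette_mask(vol, np.zeros((3, 3, 3))).data == 0)

    def test_outside_spike_removed_inside_untouched(self, rng):
        data = rng.random((4, 4, 4))
        sil = np.ones((4, 4, 4), dtype=np.uint8)
        sil[0, 0, 0] = 0
        data[0, 0, 0] = 99.0  # outlier outside the silhouette
        out = silhouette_mask(self._indexed(data), sil)
        assert out.data[0, 0, 0] == 0.0
        inside = sil > 0
        np.testing.assert_array_equal(out.data[inside], data[inside])

    def test_silhouette_fills_interior_holes(self):
        template = np.zeros((8, 8, 2))
        template[1:7, 1:7, :] = 1.0
        template[3, 3, :] = 0.0  # interior low-signal voxel
        sil = compute_silhouette(template)
        assert sil[3, 3, 0] == 1
        assert sil[0, 0, 0] == 0


class TestGradientFidelity:
    def test_cam_weights_match_finite_differences_on_toy_model(self, rng):
        model = ToyCAMModel(seed=3)
        x = rng.random((6, 6, 6, 1))
        stack = extract_features_and_grads(model, x, SurvivalLabel.MEDIUM)
        assert stack.n_maps == 2
        assert (stack.activations >= 0).all()  # post-ReLU
        alpha = cam_weights(stack)
        # finite-difference oracle: perturb every activation voxel
        eps = 1e-5
        fd = np.zeros(2)
        acts = stack.activations
        for k in range(2):
            total = 0.0
            for idx in np.ndindex(acts.shape[:3]):
                up, down = acts.copy(), acts.copy()
                up[idx + (k,)] += eps
                down[idx + (k,)] -= eps
                total += (model.head_forward(up)[0, 1]
                          - model.head_forward(down)[0, 1]) / (2 * eps)
            fd[k] = total / stack.Z
        np.testing.assert_allclose(alpha, fd, rtol=1e-3, atol=1e-9)

    def test_pipeline_nonnegative_at_every_stage(self, rng):
        model = ToyCAMModel(seed=5)
        x = rng.random((6, 6, 6, 1))
        stack = extract_features_and_grads(model, x, SurvivalLabel.SHORT)
        cam = cam_combine(cam_weights(stack), stack)
        assert (cam.data >= 0).all()
        res = resample_align(cam, VolumeGrid(shape=(12, 12, 10)))
        assert (res.data >= 0).all()
        avg = class_average([res], SurvivalLabel.SHORT)
        idx = index_to_template(avg, VolumeGrid(shape=(12, 12, 14)), (2, 12))
        masked = silhouette_mask(idx, np.ones((12, 12, 14)))
        assert (masked.data >= 0).all()
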
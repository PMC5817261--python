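"""Loss, class weights, patch balancing, V-Net/W-Net mechanics, training."""

import numpy as np
import pytest

from petctseg import segmentation as seg
from petctseg.segmentation import (
    NetworkSpec,
    TrainingSchedule,
    build_vnet,
    build_wnet,
    class_weights,
    extract_patches,
    select_top_patches,
    weighted_cross_entropy,
)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        t = np.array([1.0, 0.0, 1.0])
        p = t.copy()
        # clipping keeps the loss within eps of exactly zero
        assert weighted_cross_entropy(p, t) < 1e-5

    def test_two_voxel_hand_value(self):
        """N=2, w=1, t=(1,0), p=(0.5,0.5) -> L = ln 2."""
        loss = weighted_cross_entropy(
            np.array([0.5, 0.5]), np.array([1.0, 0.0])
        )
        assert loss == pytest.approx(np.log(2.0), rel=1e-10)

    def test_inverse_frequency_ratio_on_ten_voxels(self):
        """10 voxels, 2 foreground: w_fg / w_bg = 8/2 = 4."""
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        w = class_weights(labels)
        assert w[1] / w[0] == pytest.approx(4.0)

    def test_matches_scalar_loop_oracle(self):
        """Vectorized Eq-style loss vs an explicit per-voxel loop, 1e-8."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, size=(5, 5, 5))
            t = (rng.random((5, 5, 5)) > 0.5).astype(float)
            w = class_weights(t) if 0 < t.sum() < t.size else np.array([1.0, 1.0])
            expected = 0.0
            for pi, ti in zip(p.ravel(), t.ravel()):
                wi = w[1] if ti else w[0]
                expected -= wi * (ti * np.log(pi) + (1 - ti) * np.log(1 - pi))
            expected /= p.size
            assert weighted_cross_entropy(p, t, w) == pytest.approx(
                expected, abs=1e-8
            )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=(4, 4, 4))
        t = (rng.random((4, 4, 4)) > 0.5).astype(float)
        w = class_weights(t)
        _, grad = weighted_cross_entropy(p, t, w, return_grad=True)
        eps = 1e-7
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            pp = p.copy()
            pp[idx] += eps
            fd = (weighted_cross_entropy(pp, t, w) - weighted_cross_entropy(p, t, w)) / eps
            assert grad[idx] == pytest.approx(fd, rel=1e-4)

    def test_shape_mismatch_and_nan_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.array([np.nan]), np.array([1.0]))


class TestClassWeights:
    def test_balanced_labels_equal_weights(self):
        w = class_weights(np.array([0, 1, 0, 1]))
        assert w[0] == w[1]

    def test_ninety_ten_split(self):
        labels = np.zeros(100)
        labels[:10] = 1
        w = class_weights(labels)
        assert w[1] / w[0] == pytest.approx(9.0)
        # normalization keeps the weighted voxel count at N
        assert w[0] * 90 + w[1] * 10 == pytest.approx(100.0)

    def test_invariant_to_voxel_permutation(self):
        rng = np.random.default_rng(2)
        labels = rng.random(200) > 0.8
        assert np.array_equal(
            class_weights(labels), class_weights(rng.permutation(labels))
        )

    def test_single_class_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            w = class_weights(np.zeros(10))
        assert np.array_equal(w, [1.0, 1.0])


class TestPatchExtraction:
    def test_volume_equal_to_patch_gives_single_patch(self):
        ps = extract_patches([np.zeros((64, 64, 64))], size=64, overlap=5)
        assert len(ps) == 1
        assert ps.patches[0].corner == (0, 0, 0)

    def test_flush_end_grid_enumeration(self):
        """123 voxels at stride 59 -> corners 0 and 59 along that axis."""
        ps = extract_patches([np.zeros((123, 64, 64))], size=64, overlap=5)
        corners_axis0 = sorted({p.corner[0] for p in ps.patches})
        assert corners_axis0 == [0, 59]

    def test_union_covers_every_voxel(self):
        shape = (40, 29, 53)
        ps = extract_patches([np.zeros(shape)], size=16, overlap=5)
        cover = np.zeros(shape, dtype=int)
        for p in ps.patches:
            ci, cj, ck = p.corner
            si, sj, sk = p.size
            cover[ci : ci + si, cj : cj + sj, ck : ck + sk] += 1
        assert cover.min() >= 1

    def test_label_ratio_recorded(self):
        lab = np.zeros((32, 32, 32))
        lab[:16, :16, :16] = 1
        ps = extract_patches([lab], size=16, overlap=0)
        ratios = {p.corner: p.label_ratio for p in ps.patches}
        assert ratios[(0, 0, 0)] == 1.0
        assert ratios[(16, 16, 16)] == 0.0


class TestTopPatchSelection:
    def test_k_larger_than_count_is_identity(self):
        ps = extract_patches([np.zeros((32, 32, 32))], size=16, overlap=5)
        sel = select_top_patches(ps, k=1000)
        assert len(sel) == len(ps)

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(4)
        lab = (rng.random((48, 48, 48)) > 0.9).astype(float)
        lab[:24, :24, :24] = 1.0  # one labeled octant
        ps = extract_patches([lab], size=16, overlap=5)
        k = 7
        sel = select_top_patches(ps, k=k)
        oracle = sorted(ps.patches, key=lambda p: (-p.label_ratio, p.corner))[:k]
        assert sorted(p.corner for p in sel.patches) == sorted(
            p.corner for p in oracle
        )

    def test_selection_enriches_foreground(self):
        rng = np.random.default_rng(5)
        lab = (rng.random((48, 48, 48)) > 0.995).astype(float)
        lab[4:12, 4:12, 4:12] = 1.0
        ps = extract_patches([lab], size=16, overlap=5)
        sel = select_top_patches(ps, k=5)
        mean_all = np.mean([p.label_ratio for p in ps.patches])
        mean_sel = np.mean([p.label_ratio for p in sel.patches])
        assert mean_sel > mean_all

    def test_selected_subset_of_extracted(self):
        ps = extract_patches([np.zeros((40, 40, 40))], size=16, overlap=5)
        sel = select_top_patches(ps, k=3)
        extracted = {(p.volume_id, p.corner) for p in ps.patches}
        assert all((p.volume_id, p.corner) in extracted for p in sel.patches)


class TestVNetMechanics:
    def test_output_shape_matches_input_and_range(self):
        net = build_vnet(NetworkSpec(depth=3, in_channels=2, base_width=4,
                                     width_cap=16), seed=0)
        x = np.random.default_rng(0).standard_normal((2, 13, 10, 9)).astype(np.float32)
        prob = net.forward(x)
        assert prob.shape == (13, 10, 9)
        assert np.all(np.isfinite(prob))
        assert prob.min() > 0.0 and prob.max() < 1.0

    def test_parameter_count_matches_closed_form(self):
        """Analytic count from the declared stage structure."""
        spec = NetworkSpec(depth=3, in_channels=2, base_width=4, width_cap=16)
        net = build_vnet(spec, seed=0)
        w = spec.stage_widths()  # [4, 8, 16]
        expected = 0
        # encoder blocks: conv3 (cin -> w_i)
        cins = [spec.in_channels] + w[1:]
        for cin, cout in zip(cins, w):
            expected += cout * (cin * 27) + cout
        # downsampling convs
        for i in range(2):
            expected += w[i + 1] * (w[i] * 27) + w[i + 1]
        # transposed convs (2^3 kernels)
        for i in range(2):
            expected += w[i] * (w[i + 1] * 8) + w[i]
        # decoder blocks: conv3 (2 w_i -> w_i)
        for i in range(2):
            expected += w[i] * (2 * w[i] * 27) + w[i]
        # 1x1x1 head
        expected += 1 * w[0] + 1
        assert net.n_parameters() == expected

    def test_network_gradient_matches_finite_differences(self):
        """End-to-end grad check in float64 on a tiny instance."""
        rng = np.random.default_rng(0)
        spec = NetworkSpec(depth=2, in_channels=2, base_width=2, width_cap=4,
                           dtype="float64")
        net = build_vnet(spec, seed=1)
        x = rng.standard_normal((2, 6, 6, 6))
        t = (rng.random((6, 6, 6)) > 0.7).astype(float)
        w = class_weights(t)
        prob = net.forward(x)
        _, g = weighted_cross_entropy(prob, t, w, return_grad=True)
        for p in net.params():
            p.grad[...] = 0
        net.backward(g)
        eps = 1e-6
        for param in net.params():
            flat = param.value.ravel()
            gflat = param.grad.ravel()
            for k in range(0, flat.size, max(flat.size // 3, 1)):
                old = flat[k]
                flat[k] = old + eps
                lp = weighted_cross_entropy(net.forward(x), t, w)
                flat[k] = old - eps
                lm = weighted_cross_entropy(net.forward(x), t, w)
                flat[k] = old
                fd = (lp - lm) / (2 * eps)
                if abs(fd) > 1e-10:
                    assert abs(fd - gflat[k]) / max(abs(fd), 1e-8) < 1e-4

    def test_conv_against_direct_convolution_oracle(self):
        from scipy.ndimage import correlate

        from petctseg.layers import Conv3d

        rng = np.random.default_rng(3)
        conv = Conv3d(2, 3, kernel=3, stride=1, rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 5, 6, 7))
        y = conv.forward(x)
        for f in range(3):
            expected = np.zeros(x.shape[1:])
            for c in range(2):
                kern = conv.weight.value[f].reshape(2, 3, 3, 3)[c]
                expected += correlate(x[c], kern, mode="constant")
            expected += conv.bias.value[f]
            np.testing.assert_allclose(y[f], expected, atol=1e-10)


class TestWNetMechanics:
    def test_default_stage_depths(self):
        w = build_wnet(seed=0)
        assert w.net1.spec.depth == 5
        assert w.net2.spec.depth == 3
        assert w.net2.spec.in_channels == 3

    def test_channel_validation(self):
        with pytest.raises(ValueError):
            build_wnet(NetworkSpec(depth=5, in_channels=2), seed=0)
        with pytest.raises(ValueError):
            build_wnet(NetworkSpec(depth=5, in_channels=1),
                       NetworkSpec(depth=3, in_channels=2), seed=0)

    def test_mask_channel_informs_stage_two(self):
        """Zeroing the skeleton-mask channel changes the stage-2 output."""
        w = build_wnet(
            NetworkSpec(depth=2, in_channels=1, base_width=2, width_cap=4),
            NetworkSpec(depth=2, in_channels=3, base_width=2, width_cap=4),
            seed=3,
        )
        rng = np.random.default_rng(0)
        ct = rng.standard_normal((8, 8, 8)).astype(np.float32)
        pet = rng.standard_normal((8, 8, 8)).astype(np.float32)
        mask = np.ones((8, 8, 8), dtype=np.float32)
        out_with = w.net2.forward(np.stack([ct, pet, mask]))
        out_without = w.net2.forward(np.stack([ct, pet, np.zeros_like(mask)]))
        assert not np.allclose(out_with, out_without)


@pytest.fixture(scope="module")
def toy_training_set():
    """Two small volumes with bright blobs as foreground."""
    rng = np.random.default_rng(7)
    volumes, labels = [], []
    for _ in range(2):
        lab = np.zeros((24, 24, 24), bool)
        c = rng.integers(8, 16, size=3)
        zz = np.indices(lab.shape)
        lab |= sum((z - ci) ** 2 for z, ci in zip(zz, c)) < 25
        vol = lab.astype(np.float32) * 2.0 + rng.standard_normal(lab.shape).astype(np.float32) * 0.1
        volumes.append(np.stack([vol, vol]))
        labels.append(lab)
    return volumes, labels


@pytest.fixture(scope="module")
def trained_toy_model(toy_training_set):
    volumes, labels = toy_training_set
    net = build_vnet(NetworkSpec(depth=2, in_channels=2, base_width=4,
                                 width_cap=8), seed=0)
    schedule = TrainingSchedule(pretrain_iterations=200, checkpoint_every=100,
                                patch_size=16, finetune_max_iters=0)
    history = seg.train(net, volumes, labels, schedule, seed=1)
    return net, history


class TestTraining:
    def test_loss_decreases_and_checkpoints_recorded(self, trained_toy_model):
        _, history = trained_toy_model
        assert history.checkpoints == [100, 200]
        assert history.train_losses[-1] < history.train_losses[0]

    def test_reproducible_given_seed(self, toy_training_set):
        volumes, labels = toy_training_set
        losses = []
        for _ in range(2):
            net = build_vnet(NetworkSpec(depth=2, in_channels=2, base_width=2,
                                         width_cap=4), seed=5)
            schedule = TrainingSchedule(pretrain_iterations=30,
                                        checkpoint_every=10, patch_size=16,
                                        finetune_max_iters=0)
            h = seg.train(net, volumes, labels, schedule, seed=9)
            losses.append(h.train_losses[-1])
        assert losses[0] == losses[1]

    def test_requires_foreground(self, toy_training_set):
        volumes, _ = toy_training_set
        empty = [np.zeros(v.shape[1:], bool) for v in volumes]
        with pytest.raises(ValueError):
            seg.train(build_vnet(NetworkSpec(depth=2, in_channels=2,
                                             base_width=2, width_cap=4)),
                      volumes, empty, TrainingSchedule(pretrain_iterations=5,
                                                       patch_size=16))


class TestPrediction:
    def test_untrained_model_refused(self):
        net = build_vnet(NetworkSpec(depth=2, in_channels=1, base_width=2,
                                     width_cap=4), seed=0)
        with pytest.raises(RuntimeError):
            seg.predict_volume(net, np.zeros((1, 16, 16, 16), np.float32))

    def test_output_shape_and_blob_recovery(self, trained_toy_model,
                                            toy_training_set):
        net, _ = trained_toy_model
        volumes, labels = toy_training_set
        mask, prob = seg.predict_volume(net, volumes[0], patch_size=16)
        assert mask.shape == labels[0].shape
        from petctseg.evaluation import dice_score

        assert dice_score(mask, labels[0]) > 80.0

    def test_stitched_equals_single_pass_for_one_patch(self, trained_toy_model,
                                                       toy_training_set):
        net, _ = trained_toy_model
        volumes, _ = toy_training_set
        mask, prob = seg.predict_volume(net, volumes[0], patch_size=24)
        direct = net.forward(volumes[0])
        np.testing.assert_allclose(prob, direct, rtol=1e-5)

    def test_background_input_yields_empty_mask(self, trained_toy_model):
        net, _ = trained_toy_model
        rng = np.random.default_rng(11)
        bg = rng.standard_normal((2, 16, 16, 16)).astype(np.float32) * 0.1
        mask, _ = seg.predict_volume(net, bg, patch_size=16)
        assert mask.mean() < 0.05
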
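"""Parallel model assembly, bilinear fusion, training plumbing."""

import numpy as np
import pytest

from painattn.model import (
    BranchDescriptor,
    CnnbBranch,
    ModelConfig,
    ParallelPainModel,
    bilinear_fuse,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)
from painattn.nn import Tensor

TINY = dict(input_size=16, cnna_stages=((4,), (8,)), resnet_widths=(4, 8),
            attention_reduction=2, spatial_kernel=3)


class TestBranchDescriptor:
    def test_vgg_requires_blurpool_and_attention(self):
        with pytest.raises(ValueError, match="blurpool"):
            BranchDescriptor(backbone="vgg16_modified", attention_order="ca_sa")
        with pytest.raises(ValueError, match="attention_order"):
            BranchDescriptor(backbone="vgg16_modified", blurpool=True)

    def test_resnet_rejects_masking_fields(self):
        with pytest.raises(ValueError, match="masking_enabled"):
            BranchDescriptor(backbone="resnet", masking_enabled=True)

    def test_unknown_backbone(self):
        with pytest.raises(ValueError, match="backbone"):
            BranchDescriptor(backbone="alexnet")

    def test_valid_descriptors_build(self):
        from painattn.model import build_branch

        cfg = ModelConfig(**TINY, seed=1)
        a = build_branch(BranchDescriptor(backbone="vgg16_modified", blurpool=True,
                                          attention_order="ca_sa", masking_enabled=True),
                         cfg)
        b = build_branch(BranchDescriptor(backbone="resnet"), cfg)
        x = Tensor(np.random.default_rng(0).normal(0, 1, (2, 3, 16, 16)))
        fa, fb = a.eval()(x), b(x)
        assert fa.shape == (2, 8) and fb.shape == (2, 8)
        assert np.all(np.isfinite(fa.data)) and np.all(np.isfinite(fb.data))


class TestBilinearFuse:
    def test_basis_vectors(self):
        assert np.allclose(bilinear_fuse([1, 0], [0, 1]), [0, 1, 0, 0])

    def test_signed_sqrt_then_normalize(self):
        assert np.allclose(bilinear_fuse([2, 0], [2, 0]), [1, 0, 0, 0])

    def test_zero_input_gives_zero_vector(self):
        out = bilinear_fuse([0.0, 0.0], [1.0, 2.0])
        assert np.allclose(out, 0.0)

    def test_dimension_is_product_and_unit_norm(self):
        rng = np.random.default_rng(1)
        fa, fb = rng.normal(0, 1, 5), rng.normal(0, 1, 7)
        out = bilinear_fuse(fa, fb)
        assert out.shape == (35,)
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        fa, fb = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        once = bilinear_fuse(fa, fb)
        # re-normalizing an already unit-norm vector changes nothing
        assert np.allclose(once / np.linalg.norm(once), once)

    def test_tensor_batch_matches_numpy_single(self):
        rng = np.random.default_rng(3)
        fa = rng.normal(0, 1, (3, 4))
        fb = rng.normal(0, 1, (3, 5))
        batched = bilinear_fuse(Tensor(fa), Tensor(fb)).data
        for i in range(3):
            assert np.allclose(batched[i], bilinear_fuse(fa[i], fb[i]), atol=1e-9)


class TestResidualIdentity:
    def test_zeroed_residual_blocks_pass_stem_features(self):
        cfg = ModelConfig(input_size=16, cnna_stages=((4,),), resnet_widths=(4, 4),
                          attention_reduction=2, spatial_kernel=3, seed=3)
        branch = CnnbBranch(cfg, np.random.default_rng(3))
        for block in branch.blocks:
            block.conv1.weight.data[:] = 0.0
            block.conv1.bias.data[:] = 0.0
            block.conv2.weight.data[:] = 0.0
            block.conv2.bias.data[:] = 0.0
        x = Tensor(np.abs(np.random.default_rng(4).normal(0, 1, (1, 3, 16, 16))))
        out = branch(x)
        # identity path: output equals stem features pooled through the
        # same pooling chain with no residual contribution
        stem = branch.pool(branch.stem(x))
        expected = stem.relu()
        for _ in branch.blocks:
            expected = branch.pool(expected)
        assert np.allclose(out.data, expected.mean(axis=(2, 3)).data)


@pytest.fixture(scope="module")
def model():
    return ParallelPainModel(ModelConfig(**TINY, seed=7))


class TestPredict:
    def test_probabilities_sum_to_one(self, model):
        img = np.random.default_rng(0).integers(0, 256, (20, 20, 3), dtype=np.uint8)
        p = predict(model, img)
        assert p.shape == (6,)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)

    def test_deterministic_in_inference(self, model):
        img = np.random.default_rng(1).integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.array_equal(predict(model, img), predict(model, img))

    def test_wrong_shape_rejected(self, model):
        with pytest.raises(ValueError, match="expected"):
            predict(model, np.zeros((16, 16), dtype=np.uint8))

    def test_pinned_head_matches_hand_softmax(self):
        cfg = ModelConfig(input_size=8, cnna_stages=((2,),), resnet_widths=(2,),
                          attention_reduction=1, spatial_kernel=3, seed=7)
        model = ParallelPainModel(cfg)
        x = np.random.default_rng(2).integers(0, 256, (8, 8, 3), dtype=np.uint8)
        from painattn.data import preprocess
        from painattn.model import bilinear_fuse as fuse

        model.eval()
        xp = Tensor(preprocess(x, 8)[None])
        fa = model.cnna(xp).data[0]
        fb = model.cnnb(xp).data[0]
        fused = fuse(fa, fb)
        logits = fused @ model.head.weight.data + model.head.bias.data
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        assert np.allclose(predict(model, x), expected)

    def test_masking_neutral_when_attention_uniform(self):
        """All-ones core mask (uniform spatial weights above threshold) leaves
        the map unchanged, so masked and unmasked models with identical
        parameters agree at inference."""
        cfg_m = ModelConfig(**TINY, masking_enabled=True, seed=11)
        cfg_n = ModelConfig(**TINY, masking_enabled=False, seed=11)
        a, b = ParallelPainModel(cfg_m), ParallelPainModel(cfg_n)
        b.load_state_dict(a.state_dict())
        img = np.random.default_rng(5).integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.allclose(predict(a, img), predict(b, img))


class TestTraining:
    def test_one_epoch_history_and_checkpoint(self, tiny_split, tmp_path):
        (train_recs, Xtr, ytr), _ = tiny_split
        model = ParallelPainModel(ModelConfig(**TINY, seed=1))
        ckpt = tmp_path / "model.npz"
        history = train(model, train_recs, epochs=1, batch_size=16, seed=2,
                        data=(Xtr[:10], ytr[:10]), val_fraction=0.0,
                        checkpoint_path=ckpt)
        assert len(history.epochs) == 1
        assert ckpt.exists()
        loaded, meta = load_checkpoint(ckpt)
        assert meta["config"]["input_size"] == 16
        img = np.random.default_rng(0).integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.allclose(predict(loaded, img), predict(model, img))

    def test_loss_decreases_on_separable_toy(self):
        rng = np.random.default_rng(6)
        n = 40
        X = rng.normal(0, 0.1, (n, 3, 16, 16))
        y = np.zeros(n, dtype=int)
        X[n // 2:, :, 4:12, 4:12] += 2.0
        y[n // 2:] = 1
        model = ParallelPainModel(ModelConfig(**TINY, n_classes=2, seed=3))
        history = train(model, [], epochs=5, batch_size=8, lr=3e-3, seed=4,
                        data=(X, y), val_fraction=0.0)
        losses = [e["loss"] for e in history.epochs]
        assert losses[-1] < losses[0]

    def test_same_seed_identical_final_loss(self, tiny_split):
        (train_recs, Xtr, ytr), _ = tiny_split
        losses = []
        for _ in range(2):
            model = ParallelPainModel(ModelConfig(**TINY, seed=5))
            history = train(model, train_recs, epochs=2, batch_size=16, seed=6,
                            data=(Xtr, ytr), val_fraction=0.1)
            losses.append(history.epochs[-1]["loss"])
        assert losses[0] == losses[1]

    def test_empty_manifest_rejected(self):
        model = ParallelPainModel(ModelConfig(**TINY, seed=1))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], epochs=1)

    def test_single_branch_arms_build_and_predict(self):
        for arm in ("cnna", "cnnb"):
            model = ParallelPainModel(ModelConfig(**TINY, arm=arm, seed=2))
            img = np.random.default_rng(1).integers(0, 256, (16, 16, 3), dtype=np.uint8)
            p = predict(model, img)
            assert p.sum() == pytest.approx(1.0)
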
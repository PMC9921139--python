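"""Generator network: shape contracts, attention behaviour, averaging rule,
and the supervised loss."""

import numpy as np
import pytest

from macs.asdb import (ASDB, FeaturePyramid, ModelConfig, SegOutput,
                       batch_to_tensor, seg_loss)
from macs.nn import functional as F
from macs.nn.autodiff import Tensor


def _input(size, n=1, seed=0):
    return Tensor(np.random.default_rng(seed).random((n, 1, size, size)))


class TestEncoder:
    @pytest.mark.parametrize("size,expected", [(256, (64, 32, 16, 8)),
                                               (64, (16, 8, 4, 2))])
    def test_pyramid_strides(self, tiny_model, size, expected):
        pyr = tiny_model.encode(_input(size))
        assert tuple(l.shape[2] for l in pyr.levels) == expected
        assert tuple(l.shape[3] for l in pyr.levels) == expected

    def test_determinism(self, tiny_model):
        a = tiny_model.encode(_input(64))
        b = tiny_model.encode(_input(64))
        for x, y in zip(a.levels, b.levels):
            np.testing.assert_array_equal(x.data, y.data)

    def test_shape_errors(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode(Tensor(np.zeros((1, 1, 64, 32))))
        with pytest.raises(ValueError):
            tiny_model.encode(Tensor(np.zeros((1, 3, 64, 64))))
        with pytest.raises(ValueError):
            tiny_model.encode(Tensor(np.zeros((1, 1, 48, 48))))

    def test_pyramid_needs_four_levels(self):
        with pytest.raises(ValueError):
            FeaturePyramid([Tensor(np.zeros((1, 1, 4, 4)))] * 3)


class TestMLF:
    def test_common_spatial_size(self, tiny_model):
        mlf = tiny_model.fuse_mlf(tiny_model.encode(_input(64)))
        assert mlf.shape[2:] == (16, 16)

    def test_zero_pyramid_zero_mlf(self, tiny_model):
        pyr = tiny_model.encode(_input(64))
        zeros = FeaturePyramid([Tensor(np.zeros(l.shape)) for l in pyr.levels])
        for conv in tiny_model.projs + [tiny_model.mlf_conv]:
            conv.bias.data[...] = 0.0
        np.testing.assert_array_equal(tiny_model.fuse_mlf(zeros).data, 0.0)

    def test_batch_permutation_equivariance(self, tiny_model):
        x = _input(64, n=3)
        mlf = tiny_model.fuse_mlf(tiny_model.encode(x)).data
        perm = [2, 0, 1]
        xp = Tensor(x.data[perm])
        mlf_p = tiny_model.fuse_mlf(tiny_model.encode(xp)).data
        np.testing.assert_allclose(mlf_p, mlf[perm], atol=1e-6)


class TestDAM:
    def _feats(self, model):
        pyr = model.encode(_input(64))
        projected = model._project(pyr)
        mlf = model.mlf_conv(F.concat(projected))
        return projected[0], mlf

    def test_identity_attention_without_residual(self):
        model = ASDB(ModelConfig(seed=0, dam_residual=False))
        level, mlf = self._feats(model)
        ones = Tensor(np.ones(level.shape))
        out = model.dam_refine(0, level, mlf, attention_override=ones)
        np.testing.assert_allclose(out.data, level.data, atol=1e-7)

    def test_null_attention_without_residual(self):
        model = ASDB(ModelConfig(seed=0, dam_residual=False))
        level, mlf = self._feats(model)
        zeros = Tensor(np.zeros(level.shape))
        out = model.dam_refine(0, level, mlf, attention_override=zeros)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_residual_preserves_level_under_null_attention(self, tiny_model):
        level, mlf = self._feats(tiny_model)
        zeros = Tensor(np.zeros(level.shape))
        out = tiny_model.dam_refine(0, level, mlf, attention_override=zeros)
        np.testing.assert_allclose(out.data, level.data, atol=1e-7)

    def test_attention_in_unit_interval(self, tiny_model):
        level, mlf = self._feats(tiny_model)
        att = tiny_model.dams[0].attention(level, mlf).data
        assert att.min() >= 0.0 and att.max() <= 1.0

    def test_spatial_mismatch_raises(self, tiny_model):
        level, mlf = self._feats(tiny_model)
        small = Tensor(mlf.data[:, :, :8, :8])
        with pytest.raises(ValueError):
            tiny_model.dams[0].attention(level, small)


class TestPredict:
    def test_fused_is_mean_of_layers(self, tiny_model):
        out = tiny_model(_input(64, n=2))
        assert len(out.per_layer_masks) == 8
        mean = np.mean([m.data for m in out.per_layer_masks], axis=0)
        np.testing.assert_allclose(out.fused_mask.data, mean, atol=1e-6)
        assert out.fused_mask.data.min() >= 0.0 and out.fused_mask.data.max() <= 1.0
        assert out.boundary.shape == (2, 1, 64, 64)

    def test_refined_only_mode_has_four_layers(self):
        model = ASDB(ModelConfig(seed=0, mask_layers="refined"))
        assert len(model(_input(64)).per_layer_masks) == 4

    def test_mean_of_constant_layers(self):
        vals = [0.2, 0.4, 0.6, 0.8]
        fused = F.mean_tensors([Tensor(np.full((1, 1, 1, 1), v)) for v in vals])
        assert fused.data.item() == pytest.approx(0.5, abs=1e-7)


class TestSegLoss:
    def _perfect_output(self, endo, epi, boundary, eps):
        target = np.stack([endo, epi], axis=1).astype(np.float32)
        probs = np.clip(target, eps, 1 - eps)
        masks = [Tensor(probs) for _ in range(8)]
        return SegOutput(per_layer_masks=masks, fused_mask=F.mean_tensors(masks),
                         fused_feature=Tensor(np.zeros((1, 1, 4, 4))),
                         boundary=Tensor(boundary[:, None]))

    def test_perfect_prediction_loss_vanishes(self, small_phantoms):
        s = small_phantoms[0]
        endo, epi = s.endo_mask[None], s.epi_mask[None]
        bnd = s.boundary_map[None]
        losses = [seg_loss(self._perfect_output(endo, epi, bnd, eps), endo, epi, bnd).item()
                  for eps in (1e-2, 1e-4, 1e-6)]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-4

    def test_single_pixel_half_prediction(self):
        endo = np.ones((1, 1, 1), dtype=bool)
        epi = np.ones((1, 1, 1), dtype=bool)
        bnd = np.zeros((1, 1, 1), dtype=np.float32)
        masks = [Tensor(np.full((1, 2, 1, 1), 0.5))]
        out = SegOutput(per_layer_masks=masks, fused_mask=masks[0],
                        fused_feature=Tensor(np.zeros((1, 1, 1, 1))),
                        boundary=Tensor(np.zeros((1, 1, 1, 1))))
        assert seg_loss(out, endo, epi, bnd).item() == pytest.approx(np.log(2), abs=1e-6)

    def test_layer_sum_scales_with_layer_count(self):
        endo = np.ones((1, 1, 1), dtype=bool)
        epi = np.ones((1, 1, 1), dtype=bool)
        bnd = np.zeros((1, 1, 1), dtype=np.float32)

        def loss_with(n_layers):
            masks = [Tensor(np.full((1, 2, 1, 1), 0.5)) for _ in range(n_layers)]
            out = SegOutput(per_layer_masks=masks, fused_mask=masks[0],
                            fused_feature=Tensor(np.zeros((1, 1, 1, 1))),
                            boundary=Tensor(np.zeros((1, 1, 1, 1))))
            return seg_loss(out, endo, epi, bnd).item()

        assert loss_with(8) == pytest.approx(2 * loss_with(4), abs=1e-6)

    def test_missing_labels_rejected(self, tiny_model):
        out = tiny_model(_input(64))
        with pytest.raises(ValueError):
            seg_loss(out, None, None, np.zeros((1, 64, 64)))

    def test_gradients_reach_every_parameter(self, tiny_model, small_phantoms):
        batch = small_phantoms[:2]
        out = tiny_model(batch_to_tensor(batch))
        endo = np.stack([s.endo_mask for s in batch])
        epi = np.stack([s.epi_mask for s in batch])
        bnd = np.stack([s.boundary_map for s in batch])
        tiny_model.zero_grad()
        seg_loss(out, endo, epi, bnd).backward()
        for name, p in tiny_model.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.abs(p.grad).max() > 0, f"zero gradient for {name}"
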
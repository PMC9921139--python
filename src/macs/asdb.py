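"""Attention Segmentation with Dual Branch (ASDB) — the generator.

A multi-scale encoder in the ResNeXt style (grouped-convolution residual
blocks) extracts four feature maps at strides 4/8/16/32.  All levels are
projected, resampled to the stride-4 grid and fused by a learned 1x1
reweighting into the multi-layer feature (MLF).  A deep attention module
(DAM) refines each projected level with an attention map computed from
the level feature and the MLF.  The mask branch predicts a 2-channel
(endocardium, epicardium) probability map from every original and
refined level and averages them; the boundary branch regresses a
contour-band map from the two highest-resolution refined levels.

Masks use two independent sigmoid channels rather than a softmax: the
epicardium region contains the endocardium region, so the classes are
nested, not mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``preset="tiny"`` is sized for desk-scale experiments on 64x64
    phantoms; ``preset="full"`` widens the encoder toward a full-size
    ResNeXt-like backbone.  ``mask_layers`` selects whether the
    per-layer mask sum runs over original+refined levels (8 terms) or
    refined levels only (4 terms).
    """

    preset: str = "tiny"
    channels: tuple[int, int, int, int] = (12, 16, 24, 32)
    proj_channels: int = 16
    groups: int = 4
    mask_layers: str = "original+refined"  # or "refined"
    dam_residual: bool = True
    boundary_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset == "full":
            self.channels = (64, 128, 256, 512)
            self.proj_channels = 64
            self.groups = 32
        if self.mask_layers not in ("original+refined", "refined"):
            raise ValueError(f"unknown mask_layers mode {self.mask_layers!r}")


@dataclass
class FeaturePyramid:
    """Four feature maps at strides 4, 8, 16, 32 relative to the input."""

    levels: list

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ValueError("a feature pyramid has exactly 4 levels")


@dataclass
class SegOutput:
    """Network outputs for one batch."""

    per_layer_masks: list          # each (N, 2, H, W) probability map
    fused_mask: Tensor             # arithmetic mean of per_layer_masks
    fused_feature: Tensor          # MLF, input to the feature discriminator
    boundary: Tensor               # (N, 1, H, W) in [0, 1]


class _ResNeXtBlock(nn.Module):
    """1x1 reduce -> grouped 3x3 (stride 2) -> 1x1 expand, with shortcut."""

    def __init__(self, cin: int, cout: int, groups: int, rng):
        width = max(groups, cout // 2 // groups * groups)
        self.reduce = nn.Conv2d(cin, width, 1, rng)
        self.grouped = nn.Conv2d(width, width, 3, rng, stride=2, groups=groups)
        self.expand = nn.Conv2d(width, cout, 1, rng)
        self.shortcut = nn.Conv2d(cin, cout, 1, rng, stride=2, padding=0)

    def forward(self, x):
        y = F.leaky_relu(self.reduce(x))
        y = F.leaky_relu(self.grouped(y))
        y = self.expand(y)
        return F.leaky_relu(y + self.shortcut(x))


class DAM(nn.Module):
    """Deep attention module: gate a level feature with MLF context.

    attention = sigmoid(conv3x3(concat(level, MLF))), applied
    multiplicatively, with an optional residual add of the level
    feature so that all-ones attention doubles and all-zeros attention
    preserves the projected level feature.
    """

    def __init__(self, channels: int, rng, residual: bool = True):
        self.att_conv = nn.Conv2d(2 * channels, channels, 3, rng)
        self.residual = residual

    def attention(self, level: Tensor, mlf: Tensor) -> Tensor:
        if level.shape[2:] != mlf.shape[2:]:
            raise ValueError("level feature and MLF must share spatial size")
        return F.sigmoid(self.att_conv(F.concat([level, mlf])))

    def forward(self, level: Tensor, mlf: Tensor,
                attention_override: Tensor | None = None) -> Tensor:
        att = attention_override if attention_override is not None \
            else self.attention(level, mlf)
        refined = level * att
        if self.residual:
            refined = refined + level
        return refined


class ASDB(nn.Module):
    """The attention dual-branch segmentation network."""

    N_LEVELS = 4

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3, c4 = cfg.channels
        pc = cfg.proj_channels
        # stem: two stride-2 convs take the input to stride 4
        self.stem1 = nn.Conv2d(1, c1, 3, rng, stride=2)
        self.stem2 = nn.Conv2d(c1, c1, 3, rng, stride=2)
        self.block2 = _ResNeXtBlock(c1, c2, cfg.groups, rng)
        self.block3 = _ResNeXtBlock(c2, c3, cfg.groups, rng)
        self.block4 = _ResNeXtBlock(c3, c4, cfg.groups, rng)
        self.projs = [nn.Conv2d(c, pc, 1, rng) for c in cfg.channels]
        self.mlf_conv = nn.Conv2d(self.N_LEVELS * pc, pc, 1, rng)
        self.dams = [DAM(pc, rng, cfg.dam_residual) for _ in range(self.N_LEVELS)]
        self.mask_heads_orig = [nn.Conv2d(pc, 2, 1, rng) for _ in range(self.N_LEVELS)]
        self.mask_heads_ref = [nn.Conv2d(pc, 2, 1, rng) for _ in range(self.N_LEVELS)]
        self.bnd_conv1 = nn.Conv2d(2 * pc, pc, 3, rng)
        self.bnd_conv2 = nn.Conv2d(pc, 1, 1, rng)

    # ------------------------------------------------------------------
    def encode(self, x: Tensor) -> FeaturePyramid:
        """Four-scale encoding of a (N, 1, H, W) batch; H = W, H % 32 == 0."""
        n, c, h, w = x.shape
        if h != w:
            raise ValueError(f"input must be square, got {h}x{w}")
        if c != 1:
            raise ValueError(f"input must be single-channel, got {c}")
        if h % 32:
            raise ValueError("input side must be divisible by 32")
        f1 = F.leaky_relu(self.stem2(F.leaky_relu(self.stem1(x))))   # stride 4
        f2 = self.block2(f1)                                         # stride 8
        f3 = self.block3(f2)                                         # stride 16
        f4 = self.block4(f3)                                         # stride 32
        return FeaturePyramid([f1, f2, f3, f4])

    def _project(self, pyramid: FeaturePyramid) -> list:
        """Project every level to proj_channels and the stride-4 grid."""
        return [F.upsample_nearest(self.projs[i](lvl), 2 ** i)
                for i, lvl in enumerate(pyramid.levels)]

    def fuse_mlf(self, pyramid: FeaturePyramid) -> Tensor:
        """Multi-layer feature: concat of resampled levels, 1x1 reweighting."""
        return self.mlf_conv(F.concat(self._project(pyramid)))

    def dam_refine(self, level_index: int, level_feature: Tensor,
                   mlf: Tensor, attention_override: Tensor | None = None) -> Tensor:
        return self.dams[level_index](level_feature, mlf, attention_override)

    # ------------------------------------------------------------------
    def forward(self, x: Tensor) -> SegOutput:
        pyramid = self.encode(x)
        projected = self._project(pyramid)
        mlf = self.mlf_conv(F.concat(projected))
        refined = [self.dams[i](projected[i], mlf) for i in range(self.N_LEVELS)]

        up = x.shape[2] // projected[0].shape[2]
        masks = []
        if self.config.mask_layers == "original+refined":
            for head, feat in zip(self.mask_heads_orig, projected):
                masks.append(F.upsample_nearest(F.sigmoid(head(feat)), up))
        for head, feat in zip(self.mask_heads_ref, refined):
            masks.append(F.upsample_nearest(F.sigmoid(head(feat)), up))
        fused = F.mean_tensors(masks)

        b = F.leaky_relu(self.bnd_conv1(F.concat([refined[0], refined[1]])))
        boundary = F.upsample_nearest(F.sigmoid(self.bnd_conv2(b)), up)
        return SegOutput(per_layer_masks=masks, fused_mask=fused,
                         fused_feature=mlf, boundary=boundary)

    predict = forward


def seg_loss(output: SegOutput, endo_mask: np.ndarray, epi_mask: np.ndarray,
             boundary_target: np.ndarray) -> Tensor:
    """Supervised loss: per-layer BCE sum plus one boundary MSE term.

    L_seg = sum_i BCE(mask_i, labels) + MSE(boundary, boundary_target),
    natural-log BCE averaged over pixels/channels/batch within each
    layer term.  Only labeled (source-domain) samples may enter.
    """
    if endo_mask is None or epi_mask is None:
        raise ValueError("seg_loss requires labeled samples (endo and epi masks)")
    target = np.stack([np.asarray(endo_mask, dtype=np.float32),
                       np.asarray(epi_mask, dtype=np.float32)], axis=1)
    loss = F.bce(output.per_layer_masks[0], target)
    for m in output.per_layer_masks[1:]:
        loss = loss + F.bce(m, target)
    bt = np.asarray(boundary_target, dtype=np.float32)
    if bt.ndim == 3:
        bt = bt[:, None]
    return loss + F.mse(output.boundary, bt)


def batch_to_tensor(samples) -> Tensor:
    """Stack ImageSamples into an (N, 1, H, W) input tensor."""
    return Tensor(np.stack([s.image for s in samples])[:, None])
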
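"""Multi-space domain discriminators and adversarial losses.

Two patch-based fully-convolutional classifiers distinguish source-
from target-domain outputs of the segmentation network: one on the
fused high-level feature (feature-space alignment), one on the entropy
map of the fused mask prediction (output-space alignment).  Their
binary cross-entropy losses use domain label 1 for source and 0 for
target; the generator's adversarial losses ask the discriminators to
call target-domain outputs "source" (label 1).

The per-pixel entropy of a mask probability p is implemented as the
nonnegative uncertainty -p*log(p) (natural log, 0*log 0 := 0); a
config flag preserves the signed convention p*log(p) instead — the sign
does not affect discriminability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor

SOURCE_LABEL = 1.0
TARGET_LABEL = 0.0


def entropy_map(probs: Tensor | np.ndarray, sign: str = "uncertainty") -> Tensor:
    """Per-pixel, per-channel entropy map E = -p*log(p) of a probability map.

    Differentiable; zero at p in {0, 1}, maximal (1/e) at p = 1/e.
    ``sign="printed"`` returns p*log(p) instead.
    """
    if sign not in ("uncertainty", "printed"):
        raise ValueError(f"unknown entropy sign convention {sign!r}")
    p = probs if isinstance(probs, Tensor) else Tensor(probs)
    if p.data.min() < -1e-6 or p.data.max() > 1.0 + 1e-6:
        raise ValueError("probabilities outside [0, 1]")
    pd = np.clip(p.data.astype(np.float64), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(pd > 0, np.log(pd), 0.0)
    ent = -pd * logp
    flip = -1.0 if sign == "printed" else 1.0
    out = Tensor(flip * ent, True, (p,))

    def _bwd(g):
        # d(-p ln p)/dp = -(ln p + 1); take 0 at p = 0 (the limit direction
        # is +inf, but a saturated prediction should not receive gradient)
        dp = np.where(pd > 0, -(logp + 1.0), 0.0)
        p.accumulate_grad(g * flip * dp)

    out._backward = _bwd
    return out


class PatchDiscriminator(nn.Module):
    """Fully-convolutional domain classifier emitting per-patch probabilities.

    Five stride-2 convolutions with leaky-rectifier activations and a
    final sigmoid; the receptive field grows to image scale while the
    output stays a small grid of patch decisions.
    """

    def __init__(self, in_channels: int, base: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [in_channels, base, 2 * base, 2 * base, 2 * base, 1]
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], 3, rng, stride=2)
                      for i in range(5)]

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs[:-1]:
            x = F.leaky_relu(conv(x), 0.2)
        return F.sigmoid(self.convs[-1](x))


@dataclass
class DiscriminatorPair:
    """Independent feature-space and output-space discriminators."""

    feature_disc: PatchDiscriminator
    entropy_disc: PatchDiscriminator

    @classmethod
    def build(cls, feature_channels: int, mask_channels: int = 2,
              base: int = 8, seed: int = 0) -> "DiscriminatorPair":
        return cls(
            feature_disc=PatchDiscriminator(feature_channels, base, seed=seed),
            entropy_disc=PatchDiscriminator(mask_channels, base, seed=seed + 1),
        )


def _check_batch(t: Tensor, name: str) -> None:
    if t.shape[0] < 1:
        raise ValueError(f"empty {name} batch")


def disc_feature_loss(feat_source: Tensor, feat_target: Tensor,
                      disc: PatchDiscriminator) -> Tensor:
    """Feature-discriminator loss: BCE(D(f_s), 1) + BCE(D(f_t), 0).

    Inputs are detached: this loss trains the discriminator only.
    """
    _check_batch(feat_source, "source")
    _check_batch(feat_target, "target")
    return (F.bce(disc(feat_source.detach()), SOURCE_LABEL)
            + F.bce(disc(feat_target.detach()), TARGET_LABEL))


def disc_entropy_loss(ent_source: Tensor, ent_target: Tensor,
                      disc: PatchDiscriminator) -> Tensor:
    """Entropy-discriminator loss: BCE(D(E_s), 1) + BCE(D(E_t), 0)."""
    _check_batch(ent_source, "source")
    _check_batch(ent_target, "target")
    return (F.bce(disc(ent_source.detach()), SOURCE_LABEL)
            + F.bce(disc(ent_target.detach()), TARGET_LABEL))


def adv_losses(feat_target: Tensor, ent_target: Tensor,
               discs: DiscriminatorPair, domain: str = "target") -> tuple[Tensor, Tensor]:
    """Generator adversarial losses on a target-domain batch.

    L_adv^f = BCE(D^f(f_t), 1) and L_adv^e = BCE(D^e(E_t), 1): the
    generator is rewarded when target outputs are mistaken for source.
    Gradients flow through the discriminators into the generator; the
    training loop must not step discriminator parameters on this pass.
    """
    if domain != "target":
        raise ValueError("adversarial losses are defined on target-domain batches only")
    _check_batch(feat_target, "target")
    _check_batch(ent_target, "target")
    return (F.bce(discs.feature_disc(feat_target), SOURCE_LABEL),
            F.bce(discs.entropy_disc(ent_target), SOURCE_LABEL))
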
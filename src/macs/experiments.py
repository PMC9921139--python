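"""Canonical desk-scale experiments on two-domain phantoms.

These functions freeze the study conditions used by the examples, the
test suite and the acceptance script: 64x64 sector phantoms, domain A
(source: gamma 1.0, speckle shape 4, texture scale 8) versus domain B
(target: gamma 0.5, speckle shape 2, texture scale 4 — a brighter,
noisier, finer-textured acquisition), the tiny model preset, and the
desk training schedule (Adam 5e-3 for the generator, SGD 1e-3 for the
discriminators, batch 8, up to 30 epochs).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .phantom import ImageSample, PhantomConfig, generate_dataset, style_shifted
from .trainer import (TrainConfig, evaluate_model, fit, summarize_records,
                      sweep_target_count)

DESK_IMAGE_SIZE = 64
DESK_EPI_MARGIN = (2, 5)
TARGET_STYLE = dict(gamma=0.5, speckle_shape=2.0, texture_scale=4.0)


def source_config(n_images: int, seed: int, image_size: int = DESK_IMAGE_SIZE) -> PhantomConfig:
    return PhantomConfig(image_size=image_size, n_images=n_images, domain="A",
                         epi_margin_range=DESK_EPI_MARGIN, seed=seed)


def target_config(n_images: int, seed: int, image_size: int = DESK_IMAGE_SIZE) -> PhantomConfig:
    cfg = style_shifted(source_config(n_images, seed, image_size),
                        domain="B", **TARGET_STYLE)
    return cfg


def two_domain_phantoms(n_source: int = 96, n_target: int = 96, n_eval: int = 32,
                        seed: int = 11, image_size: int = DESK_IMAGE_SIZE):
    """(source labeled, target pool, labeled target eval set).

    The three sets use disjoint seeds derived from `seed`; the target
    pool and eval set share the domain-B style but not geometry.
    """
    source = generate_dataset(source_config(n_source, seed, image_size))
    target = generate_dataset(target_config(n_target, seed + 200, image_size))
    target_eval = generate_dataset(target_config(n_eval, seed + 300, image_size))
    return source, target, target_eval


def _mean_dice(summary: dict) -> float:
    return 0.5 * (summary["endo"]["di"] + summary["epi"]["di"])


def train_arm(arm: str, source, target, target_eval, seed: int,
              epochs: int = 30) -> dict:
    """Train one ablation arm and evaluate on the labeled target set."""
    cfg = TrainConfig.desk(epochs=epochs, val_every=10, ablation=arm, seed=seed)
    result = fit(cfg, source, target if arm != "no_da" else ())
    summary = summarize_records(evaluate_model(result.model, target_eval,
                                               batch_size=cfg.batch_size))
    return {"arm": arm, "seed": seed, "source_val_dice": result.best_val_dice,
            "target_mean_dice": _mean_dice(summary), "summary": summary}


def domain_adaptation_comparison(seeds=(0, 1, 2), arms=("no_da", "full"),
                                 n_source: int = 96, n_target: int = 96,
                                 n_eval: int = 32, data_seed: int = 11,
                                 epochs: int = 30) -> dict:
    """Target-domain Dice of adversarial arms versus source-only training.

    Returns per-seed rows and the per-arm mean target Dice — the
    desk-scale analogue of the ablation table's headline comparison.
    """
    source, target, target_eval = two_domain_phantoms(n_source, n_target,
                                                      n_eval, data_seed)
    rows = [train_arm(arm, source, target, target_eval, seed, epochs)
            for seed in seeds for arm in arms]
    means = {arm: float(np.mean([r["target_mean_dice"] for r in rows
                                 if r["arm"] == arm])) for arm in arms}
    return {"rows": rows, "mean_target_dice": means}


def learning_sanity(n_source: int = 50, seed: int = 0, epochs: int = 30,
                    data_seed: int = 11) -> dict:
    """Source-only training must lift validation Dice above its value at
    initialisation."""
    source = generate_dataset(source_config(n_source, data_seed))
    cfg = TrainConfig.desk(epochs=epochs, val_every=10, ablation="no_da", seed=seed)
    result = fit(cfg, source)
    initial = result.history[0]["val_dice"]
    final = max(h["val_dice"] for h in result.history if "val_dice" in h)
    return {"initial_val_dice": initial, "best_val_dice": final,
            "history": result.history}


def target_count_sweep(counts=(25, 50, 100), seed: int = 0, data_seed: int = 11,
                       epochs: int = 30) -> list[dict]:
    """Table-2-analogue: target Dice as the unlabeled pool grows."""
    source, target, target_eval = two_domain_phantoms(96, max(counts), 32, data_seed)
    cfg = TrainConfig.desk(epochs=epochs, val_every=10, seed=seed)
    return sweep_target_count(counts, cfg, source, target, target_eval)
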
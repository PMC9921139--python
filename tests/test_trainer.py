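"""Training loop: loss bookkeeping, ablation switches, schedules,
determinism and the target-count sweep."""

import dataclasses
import hashlib

import numpy as np
import pytest

from macs.phantom import PhantomConfig, generate_dataset, style_shifted
from macs.trainer import (TrainConfig, Trainer, evaluate_model, fit,
                          summarize_records, sweep_target_count)


def _datasets(n_source=20, n_target=12):
    src = generate_dataset(PhantomConfig(image_size=64, n_images=n_source,
                                         epi_margin_range=(2, 5), seed=31))
    if n_target == 0:
        return src, []
    tgt_cfg = style_shifted(PhantomConfig(image_size=64, n_images=n_target,
                                          epi_margin_range=(2, 5), seed=77),
                            gamma=0.5, speckle_shape=2.0, domain="B")
    return src, generate_dataset(tgt_cfg)


def _hash_params(module) -> str:
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(p.data.tobytes())
    return h.hexdigest()


def _cfg(**kw):
    base = dict(epochs=2, val_every=1, seed=0)
    base.update(kw)
    return TrainConfig.desk(**base)


class TestTrainStep:
    def test_total_loss_identity(self):
        src, tgt = _datasets()
        trainer = Trainer(_cfg())
        for i in range(4):
            rep = trainer.train_step(src[i * 4:(i + 1) * 4], tgt[i * 3:(i + 1) * 3])
            expected = rep.l_seg + trainer.cfg.lambda_adv * (rep.l_advf + rep.l_adve)
            assert rep.l_total == pytest.approx(expected, rel=1e-12)
            assert all(np.isfinite(v) for v in vars(rep).values())

    def test_lambda_zero_matches_pure_segmentation_update(self):
        src, tgt = _datasets(12, 8)
        t_full = Trainer(_cfg(lambda_adv=0.0))
        t_seg = Trainer(_cfg(ablation="no_da"))
        for step in range(2):
            sb = src[step * 6:(step + 1) * 6]
            rep_full = t_full.train_step(sb, tgt[:6])
            rep_seg = t_seg.train_step(sb, [])
            assert rep_full.l_total == rep_full.l_seg
            assert rep_full.l_seg == rep_seg.l_seg
        assert _hash_params(t_full.model) == _hash_params(t_seg.model)

    def test_no_da_arm_never_touches_discriminators(self):
        src, tgt = _datasets(16, 8)
        trainer = Trainer(_cfg(ablation="no_da"))
        before_f = _hash_params(trainer.discs.feature_disc)
        before_e = _hash_params(trainer.discs.entropy_disc)
        for i in range(10):
            trainer.train_step([src[i % len(src)]], [])
        assert _hash_params(trainer.discs.feature_disc) == before_f
        assert _hash_params(trainer.discs.entropy_disc) == before_e

    @pytest.mark.parametrize("arm,df_moves,de_moves", [
        ("full", True, True), ("no_eda", True, False), ("no_fda", False, True)])
    def test_ablation_arms_update_expected_discriminators(self, arm, df_moves, de_moves):
        src, tgt = _datasets(8, 8)
        trainer = Trainer(_cfg(ablation=arm))
        before_f = _hash_params(trainer.discs.feature_disc)
        before_e = _hash_params(trainer.discs.entropy_disc)
        rep = trainer.train_step(src[:4], tgt[:4])
        assert (_hash_params(trainer.discs.feature_disc) != before_f) == df_moves
        assert (_hash_params(trainer.discs.entropy_disc) != before_e) == de_moves
        assert (rep.l_advf > 0) == df_moves
        assert (rep.l_adve > 0) == de_moves

    def test_adversarial_arm_requires_target_batch(self):
        src, _ = _datasets(8, 1)
        trainer = Trainer(_cfg(ablation="full"))
        with pytest.raises(ValueError):
            trainer.train_step(src[:4], [])

    def test_determinism_of_loss_sequence(self):
        src, tgt = _datasets(16, 8)
        reports = []
        for _ in range(2):
            trainer = Trainer(_cfg())
            reports.append([trainer.train_step(src[i * 4:(i + 1) * 4], tgt[:4])
                            for i in range(3)])
        for a, b in zip(*reports):
            assert vars(a) == vars(b)


class TestFit:
    def test_validation_schedule(self):
        src, _ = _datasets(12, 0)
        res = fit(_cfg(epochs=1, val_every=1, ablation="no_da"), src)
        training_vals = [h for h in res.history if h["epoch"] >= 1 and "val_dice" in h]
        assert len(training_vals) == 1
        assert "val_dice" in res.history[0] and res.history[0]["epoch"] == 0

    def test_disc_lr_schedule(self):
        trainer = Trainer(TrainConfig(seed=0))  # decay 0.2 every 100 epochs
        trainer.set_epoch(0)
        assert trainer.df_opt.lr == pytest.approx(1e-3)
        trainer.set_epoch(100)
        assert trainer.df_opt.lr == pytest.approx(2e-4)
        assert trainer.de_opt.lr == pytest.approx(2e-4)

    def test_fit_reproducible(self):
        src, tgt = _datasets(16, 8)
        h1 = fit(_cfg(), src, tgt).history
        h2 = fit(_cfg(), src, tgt).history
        assert h1 == h2

    def test_validation_split_too_small(self):
        src, _ = _datasets(2, 0)
        with pytest.raises(ValueError):
            fit(dataclasses.replace(_cfg(ablation="no_da"), val_fraction=0.9), src[:2])

    def test_evaluate_model_records(self, small_phantoms):
        src, _ = _datasets(12, 0)
        res = fit(_cfg(epochs=1, ablation="no_da"), src)
        records = evaluate_model(res.model, small_phantoms[:4])
        assert len(records) == 8  # 2 structures x 4 images
        summary = summarize_records(records)
        assert set(summary) == {"endo", "epi"}
        for mets in summary.values():
            assert 0.0 <= mets["di"] <= 1.0
            assert mets["ji"] <= mets["di"] + 1e-12


class TestSweep:
    def test_zero_count_degenerates_to_source_only(self):
        src, tgt = _datasets(14, 6)
        rows = sweep_target_count([0], _cfg(epochs=1), src, tgt, src[:3])
        assert {r["n_target"] for r in rows} == {0}
        assert len(rows) == 2

    def test_excessive_count_rejected(self):
        src, tgt = _datasets(8, 4)
        with pytest.raises(ValueError):
            sweep_target_count([99], _cfg(epochs=1), src, tgt, src[:2])

    def test_sweep_reproducible(self):
        src, tgt = _datasets(14, 8)
        r1 = sweep_target_count([4], _cfg(epochs=1), src, tgt, src[:3])
        r2 = sweep_target_count([4], _cfg(epochs=1), src, tgt, src[:3])
        assert r1 == r2

    def test_subsampling_without_replacement(self):
        """n_target_images = pool size consumes every pool image exactly once."""
        src, tgt = _datasets(14, 6)
        cfg = dataclasses.replace(_cfg(epochs=1), n_target_images=6)
        res = fit(cfg, src, tgt)  # would raise on duplicate/missing indices
        assert res.history
        with pytest.raises(ValueError):
            fit(dataclasses.replace(cfg, n_target_images=7), src, tgt)
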
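"""Training loop: schedule, determinism, optimisation behaviour, ablation."""

import dataclasses

import numpy as np
import pytest

from medsrnet.config import (DiscriminatorSpec, GeneratorSpec, LossWeights,
                             PhantomSpec, TrainingConfig)
from medsrnet.degradation import PairedSample, downscale_bicubic
from medsrnet.generator import build_generator, generator_forward
from medsrnet.phantom import generate_dataset, generate_phantom
from medsrnet.training import (load_checkpoint, lr_at_epoch, make_state,
                               run_ablation, save_checkpoint, train,
                               train_step)


def _pairs(n=1, size=32, scale=4, seed=0):
    hrs = generate_dataset(n, PhantomSpec(size=size, n_ellipses=2,
                                          n_lesions=2), seed=seed)
    return [PairedSample(lr=downscale_bicubic(h, scale), hr=h, scale=scale)
            for h in hrs]


def _tiny_config(**kw):
    base = dict(mode="mse_only", total_epochs=1, batch_size=2, hr_patch=32,
                initial_lr=1e-3, halving_interval=50, seed=0)
    base.update(kw)
    return TrainingConfig(**base)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 1e-4), (49, 1e-4), (50, 5e-5), (150, 1.25e-5)])
    def test_halving_closed_form(self, epoch, expected):
        cfg = TrainingConfig()
        assert lr_at_epoch(cfg, epoch) == pytest.approx(expected, rel=1e-12)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainingConfig(total_epochs=10), 10)

    def test_log_follows_schedule(self, tiny_gen_spec):
        cfg = _tiny_config(total_epochs=3, halving_interval=2)
        _, log = train(cfg, tiny_gen_spec, None, _pairs())
        for rec in log.records:
            assert rec.lr == lr_at_epoch(cfg, rec.epoch)


class TestTrainStep:
    def test_zero_learning_rate_is_noop(self, tiny_gen_spec):
        pairs = _pairs()
        gen = build_generator(tiny_gen_spec, 4, seed=0)
        state = make_state(gen, None, _tiny_config())
        before = {k: v.copy() for k, v in gen.state_dict().items()}
        train_step(state, pairs, LossWeights(1.0, 0.0), lr=0.0,
                   mode="mse_only")
        after = gen.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_step_is_deterministic(self, tiny_gen_spec):
        pairs = _pairs()
        results = []
        for _ in range(2):
            gen = build_generator(tiny_gen_spec, 4, seed=0)
            state = make_state(gen, None, _tiny_config())
            train_step(state, pairs, LossWeights(1.0, 0.0), lr=1e-3,
                       mode="mse_only")
            results.append(gen.state_dict())
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])

    def test_mse_mode_reduces_content_loss_on_fixed_batch(self, tiny_gen_spec):
        pairs = _pairs()
        gen = build_generator(tiny_gen_spec, 4, seed=0)
        state = make_state(gen, None, _tiny_config())
        losses = [train_step(state, pairs, LossWeights(1.0, 0.0), lr=1e-3,
                             mode="mse_only").content for _ in range(50)]
        early = np.mean(losses[:10])
        late = np.mean(losses[-10:])
        assert late < early

    def test_gan_mode_updates_both_networks_and_stays_finite(self,
                                                             tiny_gen_spec):
        pairs = _pairs()
        gen = build_generator(tiny_gen_spec, 4, seed=0)
        from medsrnet.discriminator import build_discriminator

        disc = build_discriminator(DiscriminatorSpec().tiny(), 32, seed=1)
        state = make_state(gen, disc, _tiny_config(mode="gan"))
        d_before = {k: v.copy() for k, v in disc.state_dict().items()}
        br = train_step(state, pairs, LossWeights(1.0, 0.001), lr=1e-4,
                        mode="gan")
        assert np.isfinite(br.total) and np.isfinite(br.discriminator)
        assert br.adversarial >= 0.0
        changed = any(np.any(d_before[k] != v)
                      for k, v in disc.state_dict().items())
        assert changed


class TestTrainLoop:
    def test_smoke_run_writes_checkpoint_and_log(self, tiny_gen_spec,
                                                 tmp_path):
        cfg = _tiny_config()
        gen, log = train(cfg, tiny_gen_spec, None, _pairs(), out_dir=tmp_path)
        assert len(log.records) == 1
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "last.npz").exists()
        assert (tmp_path / "log.csv").read_text().count("\n") == 2

    def test_identical_seed_gives_identical_log(self, tiny_gen_spec):
        cfg = _tiny_config(total_epochs=2)
        _, log_a = train(cfg, tiny_gen_spec, None, _pairs())
        _, log_b = train(cfg, tiny_gen_spec, None, _pairs())
        assert log_a.records == log_b.records

    def test_checkpoint_round_trip_preserves_forward(self, tiny_gen_spec,
                                                     tmp_path):
        cfg = _tiny_config()
        gen, _ = train(cfg, tiny_gen_spec, None, _pairs())
        path = save_checkpoint(tmp_path / "g.npz", gen)
        loaded = load_checkpoint(path)
        lr = np.random.default_rng(0).random((8, 8))
        np.testing.assert_array_equal(generator_forward(gen, lr),
                                      generator_forward(loaded, lr))


class TestAblation:
    def test_head_parameter_ordering_and_rows(self, tiny_gen_spec):
        cfg = _tiny_config(total_epochs=2)
        table = run_ablation(["bilinear_multires_agg", "deconv_agg"], cfg,
                             _pairs(), gen_spec=tiny_gen_spec)
        assert list(table["variant"]) == ["bilinear_multires_agg",
                                          "deconv_agg"]
        by = table.set_index("variant")
        assert (by.loc["deconv_agg", "head_parameters"]
                > by.loc["bilinear_multires_agg", "head_parameters"])
        assert np.isfinite(by["psnr"]).all()

    def test_repeated_variant_identical_rows(self, tiny_gen_spec):
        cfg = _tiny_config()
        t1 = run_ablation(["deconv_agg"], cfg, _pairs(),
                          gen_spec=tiny_gen_spec)
        t2 = run_ablation(["deconv_agg"], cfg, _pairs(),
                          gen_spec=tiny_gen_spec)
        assert t1.equals(t2)

    def test_unknown_variant_rejected(self, tiny_gen_spec):
        with pytest.raises(ValueError):
            run_ablation(["bogus"], _tiny_config(), _pairs(),
                         gen_spec=tiny_gen_spec)
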
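"""Loss composition, progressive schedule, and the training loop contract."""

import numpy as np
import pytest

from anodet.exceptions import ConfigurationError, ContractViolationError
from anodet.fixtures import PhantomSpec, generate_phantom
from anodet.networks import NetworkConfig
from anodet.nn import Tensor
from anodet.training import (TrainConfig, alpha_gan_losses,
                             progressive_schedule, train)
from conftest import StubModel

LOG2 = float(np.log(2.0))


def batch_of(n=4, res=4, seed=0):
    rng = np.random.default_rng(seed)
    return Tensor(rng.uniform(-1, 1, (n, 1, res, res)).astype(np.float64))


def prior_of(n=4, dim=128, seed=1):
    return Tensor(np.random.default_rng(seed).standard_normal((n, dim)))


class TestAlphaGanLosses:
    def test_perfect_autoencoder_has_zero_reconstruction(self):
        losses = alpha_gan_losses(batch_of(), StubModel(), prior_of(),
                                  TrainConfig(epochs=1))
        assert losses["reconstruction"].item() == 0.0

    def test_zero_logit_critics_give_log2_per_binary_logistic_term(self):
        losses = alpha_gan_losses(batch_of(), StubModel(), prior_of(),
                                  TrainConfig(epochs=1))
        # discriminator: real + two fake streams, each -log sigma(0) = log 2
        assert losses["discriminator"].item() == pytest.approx(3 * LOG2)
        # code discriminator: prior + encoded stream
        assert losses["code_discriminator"].item() == pytest.approx(2 * LOG2)
        # encoder/generator acceptance terms, log 2 each
        assert losses["generator"].item() == pytest.approx(2 * LOG2)
        assert losses["encoder"].item() == pytest.approx(LOG2)

    def test_lambda_rec_scales_only_the_reconstruction_component(self):
        stub = StubModel(generate_fn=lambda z: Tensor(np.zeros((4, 1, 4, 4))))
        batch = batch_of()
        one = alpha_gan_losses(batch, stub, prior_of(),
                               TrainConfig(epochs=1, lambda_rec=1.0))
        two = alpha_gan_losses(batch, stub, prior_of(),
                               TrainConfig(epochs=1, lambda_rec=2.0))
        assert two["reconstruction"].item() == pytest.approx(
            2 * one["reconstruction"].item())
        adv_one = one["generator"].item() - one["reconstruction"].item()
        adv_two = two["generator"].item() - two["reconstruction"].item()
        assert adv_one == pytest.approx(adv_two)

    def test_all_losses_finite_on_real_model(self):
        from anodet.networks import AlphaGanModel
        model = AlphaGanModel.build(NetworkConfig(max_resolution=4), seed=0)
        losses = alpha_gan_losses(
            Tensor(batch_of(res=4).data.astype(np.float32)), model,
            Tensor(prior_of().data.astype(np.float32)), TrainConfig(epochs=1))
        for value in losses.values():
            assert np.isfinite(value.item())


class TestProgressiveSchedule:
    def test_full_ladder_to_256(self):
        phases = progressive_schedule(TrainConfig(epochs=50), 256)
        assert len(phases) == 50
        assert (phases[0].resolution, phases[0].fade) == (4, False)
        # six doublings: fade/stabilize pairs through epoch 13
        assert [p.resolution for p in phases[:13]] == \
            [4, 8, 8, 16, 16, 32, 32, 64, 64, 128, 128, 256, 256]
        assert all(p.resolution == 256 and not p.fade for p in phases[12:])
        assert phases[11].fade and phases[11].resolution == 256

    def test_degenerate_flat_schedule_at_4(self):
        phases = progressive_schedule(TrainConfig(epochs=5), 4)
        assert all(p.resolution == 4 and not p.fade for p in phases)

    def test_max_resolution_8_pattern(self):
        phases = progressive_schedule(TrainConfig(epochs=6), 8)
        plan = [(p.resolution, p.fade) for p in phases]
        assert plan == [(4, False), (8, True), (8, False),
                        (8, False), (8, False), (8, False)]

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            progressive_schedule(TrainConfig(epochs=4), 32)


def phantom_records(kind, n, res, seed0):
    return [generate_phantom(PhantomSpec(res, seed0 + i, kind))
            for i in range(n)]


class TestTrain:
    def test_abnormal_in_training_set_rejected(self):
        train_records = phantom_records("none", 3, 4, 0) + \
            phantom_records("focal_blob", 1, 4, 50)
        val = phantom_records("none", 2, 4, 10) + \
            phantom_records("inversion", 2, 4, 60)
        with pytest.raises(ContractViolationError):
            train(train_records, val, NetworkConfig(max_resolution=4),
                  TrainConfig(epochs=1, batch_size=2, seed=0))

    def test_single_epoch_smoke_run_returns_checkpoint(self):
        train_records = phantom_records("none", 6, 4, 0)
        val = phantom_records("none", 2, 4, 10) + \
            phantom_records("inversion", 2, 4, 60)
        result = train(train_records, val, NetworkConfig(max_resolution=4),
                       TrainConfig(epochs=1, batch_size=2, seed=0))
        assert len(result.checkpoints) == 1
        assert result.best.epoch == 1
        assert 0.0 <= result.best.validation_auroc <= 1.0

    def test_checkpoint_count_and_loss_log(self):
        train_records = phantom_records("none", 8, 8, 0)
        val = phantom_records("none", 2, 8, 20) + \
            phantom_records("focal_blob", 2, 8, 70)
        result = train(train_records, val, NetworkConfig(max_resolution=8),
                       TrainConfig(epochs=4, batch_size=4, seed=1))
        assert [c.epoch for c in result.checkpoints] == [1, 2, 3, 4]
        for row in result.log:
            for key, value in row.items():
                if key.startswith("loss_"):
                    assert np.isfinite(value)

    def test_best_checkpoint_selection_ignores_curriculum_epochs(self):
        # schedule for max_resolution 8 stabilizes at epoch 3; even if an
        # earlier epoch had higher validation AUROC it is not a candidate
        train_records = phantom_records("none", 8, 8, 0)
        val = phantom_records("none", 3, 8, 20) + \
            phantom_records("inversion", 3, 8, 70)
        result = train(train_records, val, NetworkConfig(max_resolution=8),
                       TrainConfig(epochs=5, batch_size=4, seed=2))
        assert result.best.epoch >= 3
        candidates = [c for c in result.checkpoints if c.epoch >= 3]
        best_auroc = max(c.validation_auroc for c in candidates)
        assert result.best.validation_auroc == best_auroc
        # earliest epoch wins on ties
        firsts = [c.epoch for c in candidates
                  if c.validation_auroc == best_auroc]
        assert result.best.epoch == min(firsts)

    def test_same_seed_reproduces_epoch_losses(self):
        train_records = phantom_records("none", 6, 4, 0)
        val = phantom_records("none", 2, 4, 10) + \
            phantom_records("rotation", 2, 4, 80)
        cfg = TrainConfig(epochs=1, batch_size=3, seed=42)
        net = NetworkConfig(max_resolution=4)
        a = train(train_records, val, net, cfg)
        b = train(train_records, val, net, cfg)
        assert a.log[0] == b.log[0]

    def test_validation_without_abnormal_rejected(self):
        train_records = phantom_records("none", 4, 4, 0)
        with pytest.raises(ConfigurationError):
            train(train_records, phantom_records("none", 2, 4, 10),
                  NetworkConfig(max_resolution=4),
                  TrainConfig(epochs=1, batch_size=2, seed=0))
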
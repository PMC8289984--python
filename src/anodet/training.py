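"""Adversarial-autoencoder training on normal-only images.

Each batch performs three alternating updates:

1. the image discriminator, trained with binary logistic loss to accept real
   images and reject both fake streams (reconstructions Gen(Enc(x)) and
   prior samples Gen(z), z ~ N(0, I));
2. the code discriminator, trained to accept prior draws and reject encoder
   codes;
3. the encoder and generator jointly, minimizing the lambda_rec-weighted
   mean pixelwise L1 reconstruction error plus non-saturating adversarial
   terms that drive the discriminator to accept both fake streams and the
   code discriminator to accept the codes.

Training follows a progressive-growing curriculum: epoch 1 at 4x4, then for
each resolution doubling one fade-in epoch (the new stage's blend weight
ramps linearly from 0 to 1 across the epoch's batches) and one
stabilization epoch, after which all remaining epochs run at the maximum
resolution.  At the end of every epoch the model is checkpointed and scored
by code-norm AUROC on the validation set; the checkpoint with the highest
validation AUROC (earliest epoch on ties) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (LABEL_NORMAL, ImageRecord, check_training_purity,
                      resample_lanczos)
from .evaluation import roc_curve
from .exceptions import ConfigurationError, TrainingDivergenceError
from .networks import AlphaGanModel, NetworkConfig, grow
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "SchedulePhase", "EpochCheckpoint", "TrainResult",
           "alpha_gan_losses", "progressive_schedule", "train"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 10
    epochs: int = 50
    adam_alpha: float = 0.0005
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    lambda_rec: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.adam_alpha <= 0:
            raise ConfigurationError("batch_size, epochs, adam_alpha must be positive")


@dataclass(frozen=True)
class SchedulePhase:
    """One epoch of the progressive-growing plan."""

    epoch: int          # 1-based
    resolution: int
    fade: bool          # True: fade_alpha ramps 0 -> 1 across the epoch


@dataclass
class EpochCheckpoint:
    epoch: int
    state: dict
    validation_auroc: float

    @property
    def resolution(self) -> int:
        return int(self.state["current_resolution"])

    def restore(self, config: NetworkConfig) -> AlphaGanModel:
        model = AlphaGanModel.build(config, seed=0)
        model.load_state(self.state)
        return model


@dataclass
class TrainResult:
    best: EpochCheckpoint
    checkpoints: list[EpochCheckpoint]
    log: list[dict] = field(default_factory=list)


def progressive_schedule(config: TrainConfig,
                         max_resolution: int) -> list[SchedulePhase]:
    """Per-epoch (resolution, fade) plan: 4x4 first, then fade+stabilize per doubling."""
    resolutions = []
    r = 4
    while r <= max_resolution:
        resolutions.append(r)
        r *= 2
    n_doublings = len(resolutions) - 1
    needed = 1 + 2 * n_doublings
    if config.epochs < needed:
        raise ConfigurationError(
            f"{config.epochs} epochs cannot reach resolution {max_resolution}; "
            f"the progressive schedule needs at least {needed}")
    phases = [SchedulePhase(1, 4, False)]
    epoch = 2
    for res in resolutions[1:]:
        phases.append(SchedulePhase(epoch, res, True))
        phases.append(SchedulePhase(epoch + 1, res, False))
        epoch += 2
    while epoch <= config.epochs:
        phases.append(SchedulePhase(epoch, max_resolution, False))
        epoch += 1
    return phases


def alpha_gan_losses(batch: Tensor, model, prior_samples: Tensor,
                     config: TrainConfig) -> dict[str, Tensor]:
    """All training losses for one batch of normal images.

    Expects an object exposing encode/generate/discriminate/discriminate_code
    on Tensors (the full model or a stub).  Returns per-network losses plus
    the weighted reconstruction component under "reconstruction".  The
    "encoder_generator" entry is the joint objective actually minimized (the
    shared reconstruction term counted once).
    """
    n = batch.shape[0]
    z_enc = model.encode(batch)
    x_rec = model.generate(z_enc)
    x_gen = model.generate(prior_samples)

    recon = config.lambda_rec * (batch - x_rec).abs().mean()

    # both fake streams share one discriminator pass; with equal stream sizes
    # 2 * mean over the concatenation equals the sum of per-stream means
    d_fakes = model.discriminate(Tensor.cat([x_rec, x_gen]))
    adv_fakes = 2.0 * d_fakes.bce_with_logits(1.0)
    adv_code = model.discriminate_code(z_enc).bce_with_logits(1.0)

    # critics see detached fakes/codes so their losses only touch critic params
    d_targets = np.concatenate(
        [np.ones(n, dtype=np.float32), np.zeros(2 * n, dtype=np.float32)])
    d_all = model.discriminate(
        Tensor.cat([batch, x_rec.detach(), x_gen.detach()]))
    loss_disc = 3.0 * d_all.bce_with_logits(d_targets[:, None])

    c_targets = np.concatenate(
        [np.ones(n, dtype=np.float32), np.zeros(n, dtype=np.float32)])
    c_all = model.discriminate_code(Tensor.cat([prior_samples, z_enc.detach()]))
    loss_code_disc = 2.0 * c_all.bce_with_logits(c_targets[:, None])

    losses = {
        "reconstruction": recon,
        "encoder": recon + adv_code,
        "generator": recon + adv_fakes,
        "encoder_generator": recon + adv_fakes + adv_code,
        "discriminator": loss_disc,
        "code_discriminator": loss_code_disc,
    }
    for name, value in losses.items():
        if not np.isfinite(value.data):
            raise TrainingDivergenceError(f"non-finite {name} loss")
    return losses


def _resolution_cache(records: list[ImageRecord]) -> dict[int, np.ndarray]:
    """Lazy per-resolution stack of record pixels, resampled by Lanczos."""
    base = np.stack([r.pixels for r in records]).astype(np.float32)
    cache = {base.shape[1]: base}

    def at(resolution: int) -> np.ndarray:
        if resolution not in cache:
            cache[resolution] = np.stack(
                [resample_lanczos(img, resolution) for img in base])
        return cache[resolution]

    return at  # type: ignore[return-value]


def _validation_auroc(model: AlphaGanModel, val_pixels: np.ndarray,
                      val_labels: list[str], batch_size: int) -> float:
    """Code-norm AUROC on the validation set (Normal negative, rest positive)."""
    norms = []
    for start in range(0, len(val_pixels), batch_size):
        codes = model.encode_images(val_pixels[start:start + batch_size])
        norms.extend(np.linalg.norm(codes, axis=1).tolist())
    scores = {str(i): s for i, s in enumerate(norms)}
    labels = {str(i): lab for i, lab in enumerate(val_labels)}
    return roc_curve(scores, labels).auroc


def train(train_records: list[ImageRecord], val_records: list[ImageRecord],
          net_config: NetworkConfig, config: TrainConfig) -> TrainResult:
    """Run the progressive schedule and select the best epoch by validation AUROC."""
    check_training_purity(train_records)
    if not any(r.label != LABEL_NORMAL for r in val_records):
        raise ConfigurationError("validation set needs abnormal records for AUROC")

    rng = np.random.default_rng(config.seed)
    model = AlphaGanModel.build(net_config, seed=int(rng.integers(0, 2**31)))
    schedule = progressive_schedule(config, net_config.max_resolution)

    opt_disc = Adam(model.discriminator.parameters(), config.adam_alpha,
                    config.adam_beta1, config.adam_beta2)
    opt_code = Adam(model.code_discriminator.parameters(), config.adam_alpha,
                    config.adam_beta1, config.adam_beta2)
    opt_eg = Adam(model.encoder.parameters() + model.generator.parameters(),
                  config.adam_alpha, config.adam_beta1, config.adam_beta2)

    train_at = _resolution_cache(train_records)
    val_at = _resolution_cache(val_records)
    val_labels = [r.label for r in val_records]

    n = len(train_records)
    checkpoints: list[EpochCheckpoint] = []
    log: list[dict] = []

    for phase in schedule:
        if phase.resolution > model.current_resolution:
            grow(model)
        if not phase.fade:
            model.fade_alpha = 1.0
        pixels = train_at(phase.resolution)
        order = rng.permutation(n)
        starts = range(0, n, config.batch_size)
        n_batches = len(starts)
        sums: dict[str, float] = {}
        for b, start in enumerate(starts):
            if phase.fade:
                model.fade_alpha = (b + 1) / n_batches
            idx = order[start:start + config.batch_size]
            batch = Tensor(pixels[idx][:, None, :, :])
            prior = Tensor(rng.standard_normal(
                (len(idx), net_config.latent_dim)).astype(np.float32))
            try:
                # One shared forward per batch. The joint encoder+generator
                # loss also deposits gradients in the critics' parameters
                # (its adversarial terms pass through them), so those are
                # cleared before the critic losses - whose graphs only touch
                # critic parameters, fakes and codes being detached - are
                # backpropagated. All gradients are taken at the pre-update
                # parameters; the three optimizers then step in order.
                losses = alpha_gan_losses(batch, model, prior, config)
                losses["encoder_generator"].backward()
                model.discriminator.zero_grad()
                model.code_discriminator.zero_grad()
                losses["discriminator"].backward()
                losses["code_discriminator"].backward()
                opt_disc.step()
                opt_code.step()
                opt_eg.step()
                _zero_all(model)
            except TrainingDivergenceError as exc:
                raise TrainingDivergenceError(
                    f"{exc} (epoch {phase.epoch}, batch {b})") from exc
            for key in ("reconstruction", "encoder_generator",
                        "discriminator", "code_discriminator"):
                sums[key] = sums.get(key, 0.0) + losses[key].item()

        auroc = _validation_auroc(model, val_at(phase.resolution), val_labels,
                                  batch_size=max(config.batch_size, 16))
        checkpoints.append(EpochCheckpoint(
            epoch=phase.epoch, state=model.state(), validation_auroc=auroc))
        log.append({"epoch": phase.epoch, "resolution": phase.resolution,
                    "fade": phase.fade, "validation_auroc": auroc,
                    **{f"loss_{k}": v / n_batches for k, v in sums.items()}})

    # Model selection considers only checkpoints that have completed the
    # growth curriculum (final resolution, past its stabilization epoch):
    # the reduced-resolution and fade phases are curriculum stages, not
    # candidate models, and evaluation is defined at the fully grown model.
    n_doublings = len([p for p in schedule if p.fade])
    first_stable = 1 + 2 * n_doublings
    candidates = [c for c in checkpoints if c.epoch >= first_stable]
    aurocs = [c.validation_auroc for c in candidates]
    best = candidates[int(np.argmax(aurocs))]  # argmax takes the earliest tie
    return TrainResult(best=best, checkpoints=checkpoints, log=log)


def _zero_all(model: AlphaGanModel) -> None:
    for p in model.all_parameters():
        p.grad = None
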
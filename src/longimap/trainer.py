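"""Per-patient adversarial training loop and ensemble prediction.

One "epoch" here is the unit the method defines: several critic updates
followed by one generator update (not a pass over a dataset — there are only
two volumes).  Defaults follow the printed training protocol:

* 1000 epochs, critic updated 5x per epoch;
* in the first 25 epochs and in every 100th epoch, 100 critic updates;
* a 10x10 square of Gaussian-filtered Gaussian noise is added to the real
  follow-up slice at a fixed position, which moves from 50% to 35% to 65% of
  the image size after 40% and 60% of the epochs and is removed after 80% —
  this guarantees a real/fake difference even for near-identical timepoints,
  the failure mode that otherwise destabilizes the critic;
* at every schedule boundary the generator is checkpointed; the final
  ensemble contains the three boundary models plus the final model, and
  prediction averages them while excluding each member at the pixels its own
  noise square occupied.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from . import nn, wgan
from .augment import AugmentConfig, apply_augmentation, sample_augmentation
from .volume_io import PatientPair, ValidationError, Volume, log_record


@dataclass
class TrainConfig:
    epochs: int = 1000
    critic_updates: int = 5
    boosted_updates: int = 100
    boost_first_epochs: int = 25
    boost_every: int = 100
    noise_change_fractions: tuple = (0.4, 0.6)
    noise_remove_fraction: float = 0.8
    noise_positions: tuple = (0.50, 0.35, 0.65)
    noise_square_px: int = 10
    noise_filter_sigma: float = 1.0
    noise_amplitude: float = 0.3
    lambda_gp: float = 10.0
    learning_rate: float = 1e-4
    critic_learning_rate: float = None   # defaults to learning_rate
    adam_betas: tuple = (0.0, 0.9)
    batch_size: int = 4
    gen_levels: int = 5
    gen_base_features: int = 32
    critic_channels: tuple = (16, 32, 64, 128, 256)
    seed: int = 0
    device: str = "cpu"   # informational; execution is CPU NumPy

    def validate(self):
        f1, f2 = self.noise_change_fractions
        fr = self.noise_remove_fraction
        if not (0 < f1 < f2 < fr < 1):
            raise ValidationError(
                "noise schedule fractions must be strictly increasing in (0,1)")
        if self.epochs < 1 or self.critic_updates < 1:
            raise ValidationError("epochs and critic_updates must be >= 1")


@dataclass
class EnsembleMember:
    state: dict                       # generator parameter snapshot
    noise_mask: Optional[np.ndarray]  # 2D bool mask of the square, or None
    epoch_saved: int


@dataclass
class EnsembleModel:
    members: list
    config: TrainConfig
    slice_shape: tuple = None


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def critic_updates_for_epoch(epoch: int, cfg: TrainConfig) -> int:
    """Critic updates in the given 0-based epoch (boosted early and each
    100th 1-based epoch)."""
    if not (0 <= epoch < cfg.epochs):
        raise ValidationError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if epoch < cfg.boost_first_epochs or (epoch + 1) % cfg.boost_every == 0:
        return cfg.boosted_updates
    return cfg.critic_updates


def _phase_boundaries(cfg: TrainConfig):
    import math
    f1, f2 = cfg.noise_change_fractions
    return (
        math.ceil(f1 * cfg.epochs),
        math.ceil(f2 * cfg.epochs),
        math.ceil(cfg.noise_remove_fraction * cfg.epochs),
    )


def noise_position_for_epoch(epoch: int, cfg: TrainConfig):
    """Active noise-square position fraction for the epoch, or None."""
    if not (0 <= epoch < cfg.epochs):
        raise ValidationError(f"epoch {epoch} outside [0, {cfg.epochs})")
    b1, b2, b3 = _phase_boundaries(cfg)
    if epoch < b1:
        return cfg.noise_positions[0]
    if epoch < b2:
        return cfg.noise_positions[1]
    if epoch < b3:
        return cfg.noise_positions[2]
    return None


def noise_square_mask(slice_shape, position_fraction, cfg: TrainConfig):
    """Boolean mask of the noise square centered at the given fraction."""
    h, w = slice_shape
    n = cfg.noise_square_px
    ci = int(round(position_fraction * h))
    cj = int(round(position_fraction * w))
    i0, j0 = ci - n // 2, cj - n // 2
    if i0 < 0 or j0 < 0 or i0 + n > h or j0 + n > w:
        raise ValidationError("noise square out of bounds")
    m = np.zeros(slice_shape, bool)
    m[i0:i0 + n, j0:j0 + n] = True
    return m


def make_noise_square(slice2d, position_fraction, cfg: TrainConfig,
                      rng: np.random.Generator):
    """Add Gaussian-filtered Gaussian noise on a fixed 10x10 square.

    Returns the modified slice and the affected pixel mask; pixels outside
    the square are untouched.
    """
    slice2d = np.asarray(slice2d)
    mask = noise_square_mask(slice2d.shape, position_fraction, cfg)
    n = cfg.noise_square_px
    patch = rng.normal(0.0, 1.0, (n, n))
    if cfg.noise_filter_sigma > 0:
        patch = ndimage.gaussian_filter(patch, cfg.noise_filter_sigma)
    out = slice2d.copy()
    out[mask] += (cfg.noise_amplitude * patch).ravel().astype(out.dtype)
    return out, mask


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _slice_batch(volume, idx):
    """Gather slices (third axis) as a (B, 1, H, W) batch."""
    return np.ascontiguousarray(
        volume[:, :, idx].transpose(2, 0, 1)[:, None]).astype(nn.DTYPE)


def train_personalized(pair: PatientPair, cfg: TrainConfig,
                       augment_cfg: AugmentConfig = None,
                       progress=None) -> EnsembleModel:
    """Train the per-patient WGAN on exactly two volumes.

    Requires a preprocessed pair (shared shape, values in [0, 1]).  Returns
    the 4-member checkpoint ensemble; fully reproducible under ``cfg.seed``.
    """
    cfg.validate()
    augment_cfg = augment_cfg or AugmentConfig()
    t1 = np.asarray(pair.tp1.values, nn.DTYPE)
    t2 = np.asarray(pair.tp2.values, nn.DTYPE)
    if t1.shape != t2.shape:
        raise ValidationError("tp1 and tp2 must share one shape")
    lo = min(t1.min(), t2.min())
    hi = max(t1.max(), t2.max())
    if lo < -1e-3 or hi > 1.0 + 1e-3:
        raise ValidationError(
            f"volumes must be preprocessed to [0, 1], got range [{lo}, {hi}]")

    h, w, nz = t1.shape
    rng = np.random.default_rng(cfg.seed)
    gen = wgan.build_generator(
        wgan.GeneratorSpec(in_size=h, levels=cfg.gen_levels,
                           base_features=cfg.gen_base_features), rng)
    critic = wgan.build_critic(
        wgan.CriticSpec(in_size=h, channels=cfg.critic_channels), rng)
    opt_g = nn.Adam(gen.params(), cfg.learning_rate, cfg.adam_betas)
    opt_c = nn.Adam(critic.params(),
                    cfg.critic_learning_rate or cfg.learning_rate,
                    cfg.adam_betas)

    def augmented(volume):
        s = sample_augmentation(augment_cfg, rng)
        return apply_augmentation(volume, s, rng)

    def draw_fake_inputs():
        v = augmented(t1)
        idx = rng.integers(0, nz, cfg.batch_size)
        return _slice_batch(v, idx)

    def draw_real(pos):
        v = augmented(t2)
        idx = rng.integers(0, nz, cfg.batch_size)
        batch = _slice_batch(v, idx)
        if pos is not None:
            for b in range(batch.shape[0]):
                batch[b, 0], _ = make_noise_square(batch[b, 0], pos, cfg, rng)
        return batch

    members = []
    prev_pos = noise_position_for_epoch(0, cfg)
    B = cfg.batch_size
    losses = {}
    t_start = time.time()
    for epoch in range(cfg.epochs):
        pos = noise_position_for_epoch(epoch, cfg)
        if pos != prev_pos:
            members.append(EnsembleMember(
                state=gen.state(),
                noise_mask=noise_square_mask((h, w), prev_pos, cfg),
                epoch_saved=epoch,
            ))
            prev_pos = pos

        n_updates = critic_updates_for_epoch(epoch, cfg)
        for _ in range(n_updates):
            fake_in = draw_fake_inputs()
            fake = fake_in + gen.forward(fake_in, train=True)
            real = draw_real(pos)
            batch = np.concatenate([real, fake], axis=0)
            scores = critic.forward(batch, train=True)
            opt_c.zero_grad()
            gy = np.concatenate([
                np.full(B, -1.0 / B, nn.DTYPE), np.full(B, 1.0 / B, nn.DTYPE)])
            critic.backward(gy, accumulate=True)
            gp = wgan.gradient_penalty(
                critic, real, fake, cfg.lambda_gp, rng, accumulate_grads=True)
            opt_c.step()
            losses["critic"] = wgan.critic_loss(scores[:B], scores[B:], gp)
            losses["gp"] = gp
            if not np.isfinite(losses["critic"]):
                raise RuntimeError(
                    f"non-finite critic loss at epoch {epoch}")

        fake_in = draw_fake_inputs()
        fmap = gen.forward(fake_in, train=True)
        fake = fake_in + fmap
        scores = critic.forward(fake, train=True)
        opt_g.zero_grad()
        gx = critic.backward(np.full(B, -1.0 / B, nn.DTYPE), accumulate=False)
        gen.backward(gx, accumulate=True)
        opt_g.step()
        losses["generator"] = wgan.generator_loss(scores)
        if not np.isfinite(losses["generator"]):
            raise RuntimeError(f"non-finite generator loss at epoch {epoch}")

        log_record({
            "event": "epoch", "epoch": epoch, "critic_updates": n_updates,
            "noise_position": pos, **{k: float(v) for k, v in losses.items()},
            "elapsed_s": round(time.time() - t_start, 2),
        }, message=None if progress is None else
            f"epoch {epoch}: critic {losses['critic']:.4f}")
        if progress is not None:
            progress(epoch, losses)

    members.append(EnsembleMember(gen.state(), None, cfg.epochs))
    return EnsembleModel(members=members, config=cfg, slice_shape=(h, w))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_map(ensemble: EnsembleModel, tp1: Volume,
                batch_slices: int = 16) -> Volume:
    """Ensemble change map for a full (un-augmented) baseline volume.

    Each member predicts every slice; the ensemble value is the per-voxel
    mean over members, excluding each member at the pixels of its own noise
    square (the mask-free final member contributes everywhere, so every voxel
    keeps at least one contributor).

    Batch normalization uses the statistics of the predicted slice batch
    itself rather than the running averages: the running statistics are
    accumulated under augmentation noise and do not transfer to the clean
    un-augmented input.  Slices are normalized in groups of ``batch_slices``.
    """
    vol = tp1.values if isinstance(tp1, Volume) else np.asarray(tp1)
    h, w, nz = vol.shape
    if ensemble.slice_shape is not None and (h, w) != tuple(ensemble.slice_shape):
        raise ValidationError(
            f"slice size {(h, w)} does not match trained size "
            f"{tuple(ensemble.slice_shape)}")
    cfg = ensemble.config
    gen = wgan.build_generator(
        wgan.GeneratorSpec(in_size=h, levels=cfg.gen_levels,
                           base_features=cfg.gen_base_features),
        np.random.default_rng(0))

    total = np.zeros(vol.shape, np.float64)
    weight = np.zeros(vol.shape, np.float64)
    for member in ensemble.members:
        gen.load_state(member.state)
        mmap = np.empty(vol.shape, np.float32)
        for start in range(0, nz, batch_slices):
            idx = np.arange(start, min(start + batch_slices, nz))
            batch = _slice_batch(vol, idx)
            out = gen.forward(batch, train=True)
            mmap[:, :, idx] = out[:, 0].transpose(1, 2, 0)
        if member.noise_mask is None:
            wvox = np.ones((h, w, 1))
        else:
            wvox = (~member.noise_mask).astype(np.float64)[:, :, None]
        total += mmap * wvox
        weight += wvox
        plain_total = mmap if member is ensemble.members[0] else plain_total + mmap
    # pixels excluded by every member (possible only in hand-built ensembles
    # without the mask-free final model) fall back to the unweighted mean
    uncovered = weight == 0
    if uncovered.any():
        total[uncovered] = plain_total[uncovered]
        weight[uncovered] = len(ensemble.members)
    out = (total / weight).astype(np.float32)
    if isinstance(tp1, Volume):
        return tp1.with_values(out)
    return Volume(out)


# ---------------------------------------------------------------------------
# checkpoint persistence
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, out_dir) -> None:
    """One .npz archive per member plus a JSON manifest."""
    from .volume_io import config_to_dict

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config_to_dict(ensemble.config),
        "slice_shape": list(ensemble.slice_shape or ()),
        "members": [],
    }
    for i, m in enumerate(ensemble.members):
        arrays = {f"p{j}": a for j, a in enumerate(m.state["params"])}
        for j, (mu, var) in enumerate(m.state["bn"]):
            arrays[f"bn{j}_mean"] = mu
            arrays[f"bn{j}_var"] = var
        if m.noise_mask is not None:
            arrays["noise_mask"] = m.noise_mask
        np.savez_compressed(out_dir / f"member_{i}.npz", **arrays)
        manifest["members"].append({
            "file": f"member_{i}.npz",
            "epoch_saved": m.epoch_saved,
            "n_params": len(m.state["params"]),
            "n_bn": len(m.state["bn"]),
            "has_noise_mask": m.noise_mask is not None,
        })
    (out_dir / "ensemble.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(model_dir) -> EnsembleModel:
    from .volume_io import config_from_dict

    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "ensemble.json").read_text())
    cfg = config_from_dict(TrainConfig, manifest["config"])
    members = []
    for rec in manifest["members"]:
        with np.load(model_dir / rec["file"]) as z:
            params = [z[f"p{j}"] for j in range(rec["n_params"])]
            bn = [(z[f"bn{j}_mean"], z[f"bn{j}_var"])
                  for j in range(rec["n_bn"])]
            mask = z["noise_mask"] if rec["has_noise_mask"] else None
        members.append(EnsembleMember(
            {"params": params, "bn": bn}, mask, rec["epoch_saved"]))
    slice_shape = tuple(manifest["slice_shape"]) or None
    return EnsembleModel(members, cfg, slice_shape)
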
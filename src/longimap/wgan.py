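"""Network definitions and Wasserstein losses with gradient penalty.

The generator is a U-Net that outputs an additive change map: the synthetic
follow-up slice is ``input + map``.  The critic is a strided-convolution
encoder scoring 2D slices with a single unbounded scalar.  Training minimizes
the Wasserstein objective

    L_critic = E[C(fake)] - E[C(real)] + lambda * E[(||grad C(x_hat)|| - 1)^2]
    L_gen    = -E[C(fake)]

with the penalty evaluated at random interpolates x_hat between real and fake
samples (the standard soft Lipschitz constraint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .volume_io import ValidationError


@dataclass
class GeneratorSpec:
    in_size: int = 256
    levels: int = 5
    base_features: int = 32
    in_channels: int = 1

    def validate(self):
        if self.in_size % 2 ** (self.levels - 1) != 0:
            raise ValidationError(
                f"in_size {self.in_size} not divisible by 2^{self.levels - 1}")


@dataclass
class CriticSpec:
    in_size: int = 256
    channels: tuple = (16, 32, 64, 128, 256)
    in_channels: int = 1
    leaky_alpha: float = 0.2

    def validate(self):
        if self.in_size % 2 ** len(self.channels) != 0:
            raise ValidationError(
                f"in_size {self.in_size} not divisible through "
                f"{len(self.channels)} stride-2 stages")


def build_generator(spec: GeneratorSpec, rng=None) -> nn.UNetGenerator:
    spec.validate()
    return nn.UNetGenerator(
        levels=spec.levels, base_features=spec.base_features,
        in_channels=spec.in_channels, rng=rng,
    )


def build_critic(spec: CriticSpec, rng=None) -> nn.SliceCritic:
    spec.validate()
    return nn.SliceCritic(
        channels=spec.channels, in_size=spec.in_size,
        in_channels=spec.in_channels, alpha=spec.leaky_alpha, rng=rng,
    )


def gradient_penalty(critic, real, fake, lambda_gp: float,
                     rng: np.random.Generator, accumulate_grads=False,
                     return_parts=False):
    """Penalty pushing the critic's gradient norm toward 1 at interpolates.

    ``critic`` must expose ``input_gradient(x) -> (grad, cache)``; when
    ``accumulate_grads`` is set it must also expose ``gp_backward`` and the
    penalty's gradient w.r.t. the critic parameters is accumulated.
    """
    real = np.asarray(real, nn.DTYPE)
    fake = np.asarray(fake, nn.DTYPE)
    if real.shape != fake.shape:
        raise ValidationError("real and fake batches must share one shape")
    if lambda_gp < 0:
        raise ValidationError("lambda_gp must be >= 0")
    B = real.shape[0]
    eps = rng.uniform(0.0, 1.0, (B,) + (1,) * (real.ndim - 1)).astype(nn.DTYPE)
    xhat = eps * real + (1.0 - eps) * fake
    g, cache = critic.input_gradient(xhat)
    norms = np.sqrt((g.astype(np.float64) ** 2).sum(axis=tuple(range(1, g.ndim)))
                    + 1e-12)
    value = float(lambda_gp * np.mean((norms - 1.0) ** 2))
    if accumulate_grads and lambda_gp > 0:
        coef = (lambda_gp * 2.0 / B) * ((norms - 1.0) / norms)
        t0 = coef.reshape((B,) + (1,) * (g.ndim - 1)).astype(nn.DTYPE) * g
        critic.gp_backward(t0, cache)
    if return_parts:
        return value, xhat, norms
    return value


def critic_loss(critic_real, critic_fake, gp: float = 0.0) -> float:
    """mean(fake scores) - mean(real scores) + gradient penalty."""
    return float(np.mean(critic_fake) - np.mean(critic_real) + gp)


def generator_loss(critic_fake) -> float:
    """-mean(fake scores): the generator wants high critic scores."""
    return float(-np.mean(critic_fake))
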
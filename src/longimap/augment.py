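"""Registration-free data augmentation.

Each training step draws an independent random rigid pose (rotation within
±15° and shift within [0, 10] voxels per axis) plus additive Gaussian noise
with variance uniform in [0, 0.1].  Because baseline and follow-up are posed
independently, the training pairs are non-registered by construction — the
property that lets the method skip co-registration entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import ValidationError, Volume


@dataclass
class AugmentConfig:
    max_rotation_deg: float = 15.0
    max_shift_px: float = 10.0     # scalar, or a per-axis (x, y, z) triple
    noise_var_max: float = 0.1
    enabled: bool = True

    def shift_bounds(self):
        s = self.max_shift_px
        return tuple(s) if isinstance(s, (tuple, list)) else (s, s, s)

    def validate(self):
        bounds = (self.max_rotation_deg, self.noise_var_max) + self.shift_bounds()
        if min(bounds) < 0:
            raise ValidationError("augmentation bounds must be non-negative")


@dataclass
class AugmentSample:
    rotation_deg: tuple   # (x, y, z) in [-max_rotation, +max_rotation]
    shift_px: tuple       # (x, y, z) in [0, max_shift]
    noise_var: float      # in [0, noise_var_max]


def sample_augmentation(cfg: AugmentConfig, rng: np.random.Generator) -> AugmentSample:
    cfg.validate()
    if not cfg.enabled:
        return AugmentSample((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), 0.0)
    rot = tuple(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg, 3))
    shift = tuple(rng.uniform(0.0, b) for b in cfg.shift_bounds())
    var = float(rng.uniform(0.0, cfg.noise_var_max))
    return AugmentSample(rot, shift, var)


def _rotation_matrix(rotation_deg):
    ax, ay, az = np.deg2rad(rotation_deg)
    Rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    Ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    Rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    return Rz @ Ry @ Rx  # x-axis rotation applied first, then y, then z


def apply_augmentation(vol, sample: AugmentSample,
                       rng: np.random.Generator = None):
    """Rotate about the volume center, shift, then add Gaussian noise.

    Accepts a :class:`Volume` or a raw 3D array and returns the same kind.
    The rotation+shift is realized as one linear-interpolation resampling
    (fill value 0); the shape never changes.
    """
    values = vol.values if isinstance(vol, Volume) else np.asarray(vol)
    out = values
    if any(sample.rotation_deg) or any(sample.shift_px):
        center = (np.asarray(values.shape) - 1) / 2.0
        R = _rotation_matrix(sample.rotation_deg)
        Rinv = R.T
        t = np.asarray(sample.shift_px, dtype=np.float64)
        offset = center - Rinv @ (center + t)
        out = ndimage.affine_transform(
            values, Rinv, offset=offset, order=1, mode="constant", cval=0.0,
            output=np.float32,
        )
    if sample.noise_var > 0:
        if rng is None:
            raise ValidationError("rng required when noise variance > 0")
        out = out + rng.normal(
            0.0, np.sqrt(sample.noise_var), values.shape
        ).astype(np.float32)
    elif out is values:
        out = values.copy()
    if isinstance(vol, Volume):
        return vol.with_values(out)
    return out
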
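"""Preprocessing chain: resample, histogram match, normalize, center, mask.

The chain mirrors what a longitudinal T1ce pair needs before per-patient
adversarial training: both volumes on one fixed grid, in one intensity frame
(the follow-up is quantile-mapped onto the baseline, since scanner units are
arbitrary), scaled to [0, 1], with the brain centered and non-brain tissue
removed via an externally produced skull-strip mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import PatientPair, ValidationError, Volume


@dataclass
class PreprocessConfig:
    target_shape: tuple = (256, 256, 128)
    hist_quantiles: int = 256
    interpolation_order: int = 1
    border_value: float = 0.0

    def validate(self):
        if any(s < 8 for s in self.target_shape):
            raise ValidationError("target_shape entries must be >= 8")
        if self.hist_quantiles < 2:
            raise ValidationError("hist_quantiles must be >= 2")


def resample(vol: Volume, cfg: PreprocessConfig = None, order=None) -> Volume:
    """Resample to ``cfg.target_shape``; spacing rescales accordingly."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if any(s <= 1 for s in vol.shape):
        raise ValidationError(f"degenerate input dimension: {vol.shape}")
    order = cfg.interpolation_order if order is None else order
    target = tuple(cfg.target_shape)
    if vol.shape == target:
        return vol.copy()
    zoom = [t / s for t, s in zip(target, vol.shape)]
    out = ndimage.zoom(
        vol.values.astype(np.float32), zoom, order=order,
        mode="nearest", grid_mode=True,
    )
    # grid_mode zoom can land a voxel off; guard the contract
    out = out[tuple(slice(0, t) for t in target)]
    affine = vol.affine.copy()
    affine[:3, :3] = affine[:3, :3] / np.asarray(zoom)[None, :]
    return Volume(out, affine)


def histogram_match(moving: Volume, reference: Volume,
                    cfg: PreprocessConfig = None) -> Volume:
    """Quantile-map ``moving`` intensities onto ``reference``'s distribution.

    A monotone piecewise-linear map through ``hist_quantiles`` quantile
    anchors; the standard registration-free way to bring two scans of
    arbitrary scanner units into one intensity frame.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    ref = reference.values
    mov = moving.values
    if np.ptp(ref) == 0:
        raise ValidationError("reference volume is constant")
    if np.ptp(mov) == 0:
        raise ValidationError("moving volume is constant")
    q = np.linspace(0.0, 1.0, cfg.hist_quantiles)
    mov_q = np.quantile(mov, q)
    ref_q = np.quantile(ref, q)
    # enforce strictly non-decreasing anchors for np.interp
    mov_q = np.maximum.accumulate(mov_q)
    ref_q = np.maximum.accumulate(ref_q)
    out = np.interp(mov.ravel(), mov_q, ref_q).reshape(mov.shape)
    return moving.with_values(out.astype(np.float32))


def normalize01(vol: Volume) -> Volume:
    """Affine rescale so the minimum maps to 0 and the maximum to 1."""
    v = vol.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValidationError("cannot normalize a constant volume")
    out = (v - lo) / (hi - lo)
    return vol.with_values(out.astype(np.float32))


def center_brain(vol: Volume, mask: Volume, border_value=0.0):
    """Translate so the mask centroid lands on the grid center (rounded)."""
    if mask.shape != vol.shape:
        raise ValidationError("mask shape does not match volume")
    m = mask.values > 0.5
    if not m.any():
        raise ValidationError("empty brain mask")
    centroid = np.array(ndimage.center_of_mass(m))
    center = (np.asarray(vol.shape) - 1) / 2.0
    shift = np.round(center - centroid).astype(int)

    def translate(values, fill):
        out = np.full_like(values, fill)
        src = [slice(max(0, -s), min(n, n - s)) for s, n in zip(shift, values.shape)]
        dst = [slice(max(0, s), min(n, n + s)) for s, n in zip(shift, values.shape)]
        out[tuple(dst)] = values[tuple(src)]
        return out

    return (
        vol.with_values(translate(vol.values, np.float32(border_value))),
        mask.with_values(translate(mask.values, np.float32(0.0))),
    )


def apply_brain_mask(vol: Volume, mask: Volume) -> Volume:
    """Zero all voxels outside the binary brain mask."""
    if mask.shape != vol.shape:
        raise ValidationError("mask shape does not match volume")
    return vol.with_values((vol.values * (mask.values > 0.5)).astype(np.float32))


def preprocess_pair(pair: PatientPair, cfg: PreprocessConfig = None,
                    assume_skull_stripped: bool = False) -> PatientPair:
    """Full chain on both timepoints.

    Order: resample -> histogram match (tp2 onto tp1) -> normalize to [0,1]
    -> center brain -> apply skull-strip mask.  If no masks are provided the
    volumes must already be skull-stripped (``assume_skull_stripped``), in
    which case nonzero voxels define the mask.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    tp1 = resample(pair.tp1, cfg)
    tp2 = resample(pair.tp2, cfg)

    def prep_mask(m, ref):
        if m is not None:
            return resample(m, cfg, order=0)
        if not assume_skull_stripped:
            raise ValidationError(
                "brain masks required unless volumes are skull-stripped")
        return ref.with_values((np.abs(ref.values) > 1e-6).astype(np.float32))

    m1 = prep_mask(pair.brain_mask_tp1, tp1)
    m2 = prep_mask(pair.brain_mask_tp2, tp2)
    s1 = (resample(pair.tumor_seg_tp1, cfg, order=0)
          if pair.tumor_seg_tp1 is not None else None)
    s2 = (resample(pair.tumor_seg_tp2, cfg, order=0)
          if pair.tumor_seg_tp2 is not None else None)

    tp2 = histogram_match(tp2, tp1, cfg)
    tp1 = normalize01(tp1)
    tp2 = normalize01(tp2)

    tp1, m1b = center_brain(tp1, m1, cfg.border_value)
    tp2, m2b = center_brain(tp2, m2, cfg.border_value)
    if s1 is not None:
        s1 = center_brain(s1, m1, cfg.border_value)[0]
    if s2 is not None:
        s2 = center_brain(s2, m2, cfg.border_value)[0]
    m1, m2 = m1b, m2b

    tp1 = apply_brain_mask(tp1, m1)
    tp2 = apply_brain_mask(tp2, m2)
    out = PatientPair(tp1, tp2, m1, m2, s1, s2)
    out.validate()
    return out
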
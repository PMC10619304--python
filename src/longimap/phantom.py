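"""Synthetic longitudinal brain phantoms with known lesion change.

The phantom emulates the intensity structure the change-mapping method relies
on in contrast-enhanced T1 imaging: an ellipsoidal "brain" of intermediate
intensity containing a darker ventricle-like structure and a bright spherical
lesion (contrast enhancement makes enhancing tumor among the brightest tissue
in the volume).  Between the two timepoints the lesion volume changes by a
known factor, the follow-up acquisition is rigidly misaligned, and additive
Gaussian noise is applied — the three properties the training procedure must
cope with.

Ground truth lives in tp1 space: voxel counts and growth/reduction masks are
computed from the voxelized lesions *before* the tp2 misalignment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import PatientPair, ValidationError, Volume


@dataclass
class PhantomParams:
    shape: tuple = (64, 64, 16)
    brain_semiaxes: tuple = (24.0, 20.0, 7.0)
    ventricle_semiaxes: tuple = (5.0, 3.0, 2.0)
    ventricle_offset: tuple = (-7.0, 0.0, 0.0)
    # off-lattice center: voxelized sphere counts then grow almost
    # continuously in the radius, so target volumes can be hit closely
    lesion_center: tuple = (36.3, 32.2, 8.4)
    lesion_radius_tp1: float = 5.0
    growth_factor: float = 1.6
    intensity_background: float = 0.0
    intensity_ventricle: float = 0.2
    intensity_brain: float = 0.5
    intensity_lesion: float = 0.9
    misalign_rotation_deg: tuple = (1.5, 1.5, 1.5)
    misalign_shift_px: tuple = (0.5, 0.5, 0.25)
    edge_smooth_sigma: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self):
        if self.growth_factor <= 0:
            raise ValidationError("growth_factor must be > 0")
        order = (self.intensity_ventricle, self.intensity_brain,
                 self.intensity_lesion)
        if not (order[0] < order[1] < order[2]):
            raise ValidationError(
                "intensities must satisfy ventricle < brain < lesion")


@dataclass
class ChangeMaskPair:
    """Ground-truth change masks in tp1 space."""

    growth: Volume
    reduction: Volume


def _ellipsoid_mask(shape, center, semiaxes):
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return d <= 1.0


def _sphere_mask(shape, center, radius):
    return _ellipsoid_mask(shape, center, (radius,) * 3)


def _radius_for_target_count(shape, center, target, r_guess):
    """Radius whose voxelization is closest to ``target`` voxels.

    Starts from the continuous-volume radius ``r1 * g^(1/3)`` and snaps to
    the midpoint between the k-th and (k+1)-th nearest lattice points, so the
    voxelized sphere contains exactly k = round(target) voxels (up to ties).
    """
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    s = np.sort(d2.ravel())
    k = int(np.clip(round(target), 1, s.size - 1))
    r2 = np.sqrt((s[k - 1] + s[k]) / 2.0)
    # fall back to the continuous radius if the snap moved it implausibly far
    if not (0.5 * r_guess <= r2 <= 2.0 * r_guess):
        return r_guess
    return float(r2)


def _rigid_transform(values, rotation_deg, shift_px, order):
    """Rotate about the grid center (x, then y, then z axis) then shift."""
    center = (np.asarray(values.shape) - 1) / 2.0
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
    R = Rz @ Ry @ Rx
    # output voxel x_out samples input at R^-1 (x_out - t - c) + c
    Rinv = R.T
    t = np.asarray(shift_px, dtype=np.float64)
    offset = center - Rinv @ (center + t)
    return ndimage.affine_transform(
        values, Rinv, offset=offset, order=order, mode="constant", cval=0.0,
        output=np.float32,
    )


def _render(params, lesion_mask, brain, ventricle):
    img = np.full(params.shape, params.intensity_background, np.float32)
    img[brain] = params.intensity_brain
    img[ventricle] = params.intensity_ventricle
    img[lesion_mask] = params.intensity_lesion
    if params.edge_smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, params.edge_smooth_sigma)
    return img


def generate_phantom_pair(params: PhantomParams):
    """Build a misaligned, noisy phantom pair with known lesion change.

    Returns ``(pair, change_masks, truth)`` where ``truth`` records the
    lesion voxel counts ``v1``/``v2`` (tp1 space, pre-misalignment) and the
    modified response class they imply.
    """
    params.validate()
    shape = params.shape
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid_mask(shape, center, params.brain_semiaxes)
    vent_center = tuple(c + o for c, o in zip(center, params.ventricle_offset))
    ventricle = _ellipsoid_mask(shape, vent_center, params.ventricle_semiaxes) & brain

    r1 = params.lesion_radius_tp1
    lesion1 = _sphere_mask(shape, params.lesion_center, r1)
    r2 = _radius_for_target_count(
        shape, params.lesion_center,
        params.growth_factor * lesion1.sum(),
        r1 * params.growth_factor ** (1.0 / 3.0))
    lesion2 = _sphere_mask(shape, params.lesion_center, r2)
    for name, les in (("tp1", lesion1), ("tp2", lesion2)):
        if np.any(les & ~brain):
            raise ValidationError(f"lesion escapes the brain ellipsoid at {name}")

    v1 = int(lesion1.sum())
    v2 = int(lesion2.sum())
    growth = lesion2 & ~lesion1
    reduction = lesion1 & ~lesion2

    img1 = _render(params, lesion1, brain, ventricle)
    img2 = _render(params, lesion2, brain, ventricle)
    seg1 = lesion1.astype(np.float32)
    seg2 = lesion2.astype(np.float32)
    mask1 = brain.astype(np.float32)
    mask2 = brain.astype(np.float32)

    rot, shift = params.misalign_rotation_deg, params.misalign_shift_px
    if any(rot) or any(shift):
        img2 = _rigid_transform(img2, rot, shift, order=1)
        seg2 = _rigid_transform(seg2, rot, shift, order=0)
        mask2 = _rigid_transform(mask2, rot, shift, order=0)

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        img1 = img1 + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)
        img2 = img2 + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)
    # the phantom emulates already-normalized data, so stay within [0, 1]
    img1 = np.clip(img1, 0.0, 1.0)
    img2 = np.clip(img2, 0.0, 1.0)

    pair = PatientPair(
        tp1=Volume(img1), tp2=Volume(img2),
        brain_mask_tp1=Volume(mask1), brain_mask_tp2=Volume(mask2),
        tumor_seg_tp1=Volume(seg1), tumor_seg_tp2=Volume(seg2),
    )
    masks = ChangeMaskPair(
        growth=Volume(growth.astype(np.float32)),
        reduction=Volume(reduction.astype(np.float32)),
    )
    from .change_analysis import RanoConfig, classify_volumes

    truth = {
        "v1": v1,
        "v2": v2,
        "growth_factor": params.growth_factor,
        "misalignment": {"rotation_deg": list(rot), "shift_px": list(shift)},
        "rano_class": classify_volumes(v1, v2, RanoConfig()),
    }
    return pair, masks, truth


def phantom_suite(seed: int = 0):
    """Deterministic battery covering growth, shrinkage and stability.

    Returns a list of ``(PatientPair, ChangeMaskPair, truth)`` covering all
    three modified response classes; identical seeds yield bitwise-identical
    volumes.
    """
    cases = []
    for i, g in enumerate((1.6, 0.4, 1.0, 1.1)):
        p = PhantomParams(growth_factor=g, seed=seed * 1000 + i)
        cases.append(generate_phantom_pair(p))
    return cases
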
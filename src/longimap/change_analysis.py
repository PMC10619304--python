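"""From a signed change map to a tumor-volume change and a response class.

The generator ensemble's change map is discretized into a ternary map
(-1 = enhancing-intensity decrease, +1 = increase), denoised by removing small
connected components and silencing the noisy border band, summed into a
predicted voxel-volume change, and finally converted into a volume-only
modification of the RANO response categories:

* response — reduction in tumor volume of more than 50%
* progression — growth in tumor volume of 25% or more
* stable disease — everything else
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import ValidationError, Volume

RESPONSE = "response"
STABLE = "stable"
PROGRESSION = "progression"
RANO_CLASSES = (RESPONSE, STABLE, PROGRESSION)


@dataclass
class RanoConfig:
    threshold: float = 0.15          # map units; strict |value| > threshold
    min_component_voxels_exclusive: int = 30   # components <= this are removed
    border_margin_px: int = 10       # voxels silenced at every face
    connectivity: int = 26           # 6, 18 or 26 neighborhood
    response_reduction_pct: float = 50.0
    progression_growth_pct: float = 25.0

    def validate(self):
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.border_margin_px < 0:
            raise ValidationError("border margin must be >= 0")
        for pct in (self.response_reduction_pct, self.progression_growth_pct):
            if not (0 < pct < 100):
                raise ValidationError("percent thresholds must lie in (0, 100)")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError("connectivity must be 6, 18 or 26")

    def structure(self):
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass
class RanoResult:
    v1_voxels: int
    delta_voxels: int
    v2_pred_voxels: int
    rano_class: str
    percent_change: float

    def to_dict(self):
        return {
            "v1_voxels": self.v1_voxels,
            "delta_voxels": self.delta_voxels,
            "v2_pred_voxels": self.v2_pred_voxels,
            "rano_class": self.rano_class,
            "percent_change": self.percent_change,
        }


def _values(x):
    return x.values if isinstance(x, Volume) else np.asarray(x)


def ternarize(change_map, cfg: RanoConfig = None) -> np.ndarray:
    """Map values strictly below -threshold to -1, above +threshold to +1."""
    cfg = cfg or RanoConfig()
    m = _values(change_map)
    out = np.zeros(m.shape, np.int8)
    out[m > cfg.threshold] = 1
    out[m < -cfg.threshold] = -1
    return out


def filter_small_components(tmap, cfg: RanoConfig = None) -> np.ndarray:
    """Zero out connected components of 30 voxels or fewer, per sign class."""
    cfg = cfg or RanoConfig()
    t = _values(tmap).astype(np.int8).copy()
    struct = cfg.structure()
    for sign in (-1, 1):
        labels, n = ndimage.label(t == sign, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes <= cfg.min_component_voxels_exclusive)
        small = small[small > 0]
        if small.size:
            t[np.isin(labels, small)] = 0
    return t


def crop_border(tmap, cfg: RanoConfig = None) -> np.ndarray:
    """Silence the noisy band within ``border_margin_px`` of any face."""
    cfg = cfg or RanoConfig()
    t = _values(tmap).astype(np.int8)
    m = cfg.border_margin_px
    if m == 0:
        return t.copy()
    if any(s <= 2 * m for s in t.shape):
        raise ValidationError(
            f"every dimension must exceed 2*margin={2*m}, got {t.shape}")
    out = np.zeros_like(t)
    out[m:-m, m:-m, m:-m] = t[m:-m, m:-m, m:-m]
    return out


def volume_change(tmap) -> int:
    """Signed sum of the ternary map: the predicted voxel-volume change."""
    return int(_values(tmap).astype(np.int64).sum())


def classify_volumes(v1: int, v2: int, cfg: RanoConfig = None) -> str:
    """Volume-only response class from baseline and follow-up voxel counts."""
    cfg = cfg or RanoConfig()
    if v1 <= 0:
        raise ValidationError("baseline tumor volume must be positive")
    if v2 < 0:
        raise ValidationError("follow-up tumor volume must be non-negative")
    if v2 < v1 * (1.0 - cfg.response_reduction_pct / 100.0):
        return RESPONSE
    if v2 >= v1 * (1.0 + cfg.progression_growth_pct / 100.0):
        return PROGRESSION
    return STABLE


def classify_rano(v1: int, v2: int, cfg: RanoConfig = None) -> RanoResult:
    cfg = cfg or RanoConfig()
    cls = classify_volumes(v1, v2, cfg)
    return RanoResult(
        v1_voxels=int(v1),
        delta_voxels=int(v2) - int(v1),
        v2_pred_voxels=int(v2),
        rano_class=cls,
        percent_change=100.0 * (v2 - v1) / v1,
    )


def analyze_map(change_map, v1: int, cfg: RanoConfig = None) -> RanoResult:
    """Full chain: ternarize -> component filter -> border crop -> sum -> class.

    Filtering precedes the crop so that the crop only silences border noise
    and cannot first shrink a genuine component below the size cutoff.
    """
    cfg = cfg or RanoConfig()
    cfg.validate()
    t = ternarize(change_map, cfg)
    t = filter_small_components(t, cfg)
    t = crop_border(t, cfg)
    # a predicted follow-up volume cannot be negative: a reduction larger
    # than the baseline volume saturates at complete disappearance
    delta = max(volume_change(t), -int(v1))
    return classify_rano(v1, v1 + delta, cfg)


def ternary_pipeline(change_map, cfg: RanoConfig = None) -> np.ndarray:
    """The intermediate denoised ternary map of :func:`analyze_map`."""
    cfg = cfg or RanoConfig()
    return crop_border(filter_small_components(ternarize(change_map, cfg), cfg), cfg)


def export_heatmaps(change_map, background, out_dir, slices=None,
                    vmax=None) -> list:
    """Write per-slice PNG overlays of the signed map on an anatomy image.

    Growth (positive map) renders hot, reduction cold, on top of the
    grayscale background volume (typically the follow-up scan).  Returns the
    written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    m = _values(change_map)
    bg = _values(background)
    if m.shape != bg.shape:
        raise ValidationError("map and background must share one shape")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if slices is None:
        slices = range(m.shape[2])
    vmax = vmax or max(float(np.abs(m).max()), 1e-6)
    paths = []
    for k in slices:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(bg[:, :, k].T, cmap="gray", origin="lower")
        overlay = np.ma.masked_inside(m[:, :, k].T, -0.05 * vmax, 0.05 * vmax)
        ax.imshow(overlay, cmap="coolwarm", vmin=-vmax, vmax=vmax,
                  alpha=0.6, origin="lower")
        ax.set_axis_off()
        path = out_dir / f"heatmap_{k:03d}.png"
        fig.savefig(path, bbox_inches="tight", dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
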
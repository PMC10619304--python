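"""Core image data model, NIfTI I/O, configuration and logging.

A :class:`Volume` is the unit of all image handling: a 3D float grid plus the
affine carried from NIfTI.  The canonical in-memory axis order is (x, y, z);
volumes are reoriented to RAS on load so that the slice axis (the third
dimension, the one the networks are trained slice-by-slice along) is
unambiguous regardless of how the file was stored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml

log = logging.getLogger("longimap")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and orientation metadata."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(
                f"Volume requires a 3D grid, got shape {self.values.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float32)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return tuple(self.values.shape)

    @property
    def spacing(self) -> tuple:
        """Voxel edge lengths in mm, from the affine column norms."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    def with_values(self, values: np.ndarray) -> "Volume":
        return Volume(values, self.affine.copy())

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.affine.copy())


@dataclass
class PatientPair:
    """Baseline (tp1) and follow-up (tp2) volumes with optional masks."""

    tp1: Volume
    tp2: Volume
    brain_mask_tp1: Optional[Volume] = None
    brain_mask_tp2: Optional[Volume] = None
    tumor_seg_tp1: Optional[Volume] = None
    tumor_seg_tp2: Optional[Volume] = None

    def members(self):
        for name in (
            "tp1", "tp2", "brain_mask_tp1", "brain_mask_tp2",
            "tumor_seg_tp1", "tumor_seg_tp2",
        ):
            v = getattr(self, name)
            if v is not None:
                yield name, v

    def validate(self):
        shapes = {v.shape for _, v in self.members()}
        if len(shapes) > 1:
            raise ValidationError(f"pair members disagree in shape: {shapes}")
        for name, v in self.members():
            if "mask" in name or "seg" in name:
                vals = np.unique(v.values)
                if not np.all(np.isin(vals, (0.0, 1.0))):
                    raise ValidationError(f"{name} is not binary")


def read_volume(path) -> Volume:
    """Load a NIfTI file as a canonically oriented float Volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 else data
    if data.ndim != 3:
        raise ValidationError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    data = data.astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: image contains NaN or Inf values")
    return Volume(data, img.affine)


def write_volume(vol: Volume, path, dtype=np.float32) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), vol.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def config_from_dict(cls, d: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in d.items():
        if k not in fields:
            raise ValidationError(f"unknown {cls.__name__} field: {k}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_yaml_config(path) -> dict:
    """Load a YAML config file of per-stage sections into a plain dict."""
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return d


def save_yaml_config(d: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=False)


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

class JsonlHandler(logging.Handler):
    """Writes structured records (dict payloads) as JSON lines."""

    def __init__(self, path):
        super().__init__()
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(self.path, "a")

    def emit(self, record):
        payload = getattr(record, "payload", None)
        if payload is None:
            payload = {"message": record.getMessage()}
        payload = dict(payload)
        payload.setdefault("level", record.levelname)
        self._fh.write(json.dumps(payload) + "\n")
        self._fh.flush()

    def close(self):
        self._fh.close()
        super().close()


def setup_logging(log_file=None, level=logging.INFO):
    """Console logging, optionally mirrored to a machine-readable JSONL file."""
    logger = logging.getLogger("longimap")
    logger.setLevel(level)
    logger.handlers = [h for h in logger.handlers if not isinstance(
        h, (logging.StreamHandler, JsonlHandler))]
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(sh)
    if log_file is not None:
        logger.addHandler(JsonlHandler(log_file))
    return logger


def log_record(payload: dict, level=logging.INFO, message=None):
    """Emit a structured record to the longimap logger."""
    log.log(level, message or json.dumps(payload), extra={"payload": payload})
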
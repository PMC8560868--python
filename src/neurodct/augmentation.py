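"""Training-set augmentation: weak Gaussian blur and random zoom in/out.

Augmented copies are used for training only; validation and test volumes are
never transformed.  The study's two operators are a fixed-sigma isotropic
Gaussian blur (sigma = 1.5 voxels) and a zoom whose scale is drawn uniformly
from the two-element set {0.99, 1.03}, restoring the original grid by
symmetric zero-padding (zoom-out) or center-cropping (zoom-in).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .cohort import Split, SubjectRecord

__all__ = [
    "AugmentationMode",
    "AugmentationConfig",
    "gaussian_blur",
    "random_zoom",
    "zoom_to_shape",
    "build_training_set",
    "AugmentationError",
]


class AugmentationMode(str, Enum):
    NONE = "none"
    BLUR = "blur"
    ZOOM = "zoom"
    COMBINED = "combined"


class AugmentationError(ValueError):
    """Invalid augmentation parameter or contract violation."""


@dataclass(frozen=True)
class AugmentationConfig:
    """Augmentation operator selection; defaults are the study's stated values."""

    mode: AugmentationMode = AugmentationMode.NONE
    blur_sigma: float = 1.5
    zoom_scales: tuple[float, float] = (0.99, 1.03)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise AugmentationError(f"blur_sigma must be positive, got {self.blur_sigma}")
        for s in self.zoom_scales:
            if not 0.5 < s < 2.0:
                raise AugmentationError(f"zoom scale {s} outside (0.5, 2)")


def gaussian_blur(v: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic 3D Gaussian blur with reflecting boundaries.

    The normalized kernel and symmetric reflection conserve total intensity.
    """
    if sigma <= 0:
        raise AugmentationError(f"sigma must be positive, got {sigma}")
    return ndimage.gaussian_filter(np.asarray(v, dtype=np.float64), sigma=sigma, mode="reflect")


def zoom_to_shape(v: np.ndarray, scale: float) -> np.ndarray:
    """Rescale by ``scale`` with trilinear interpolation, then restore the
    original shape by center-cropping (scale > 1) or symmetric zero-padding
    (scale < 1)."""
    if not 0.5 < scale < 2.0:
        raise AugmentationError(f"scale {scale} outside (0.5, 2)")
    v = np.asarray(v, dtype=np.float64)
    if scale == 1.0:
        return v.copy()
    zoomed = ndimage.zoom(v, scale, order=1)
    out = np.zeros_like(v)
    # per-axis symmetric crop/pad back to the input grid
    src_slices, dst_slices = [], []
    for n_out, n_z in zip(v.shape, zoomed.shape):
        if n_z >= n_out:  # crop center
            start = (n_z - n_out) // 2
            src_slices.append(slice(start, start + n_out))
            dst_slices.append(slice(0, n_out))
        else:  # pad symmetric
            start = (n_out - n_z) // 2
            src_slices.append(slice(0, n_z))
            dst_slices.append(slice(start, start + n_z))
    out[tuple(dst_slices)] = zoomed[tuple(src_slices)]
    return out


def random_zoom(
    v: np.ndarray, scales: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Zoom by one scale picked uniformly from ``scales``; deterministic given
    the generator state."""
    scale = scales[int(rng.integers(len(scales)))]
    return zoom_to_shape(v, scale)


def build_training_set(
    records: list[SubjectRecord], cfg: AugmentationConfig
) -> list[SubjectRecord]:
    """Assemble the augmented training set.

    ``none`` passes originals through unchanged; ``blur`` / ``zoom`` yield one
    transformed copy per original (originals excluded); ``combined`` yields one
    blurred plus one zoomed copy per original, doubling the single-mode size.
    Only records with split ``train`` are accepted.
    """
    for rec in records:
        if rec.split is not Split.TRAIN:
            raise AugmentationError(
                f"subject {rec.subject_id!r} has split {rec.split.value!r}; "
                "only train records may be augmented"
            )
    if cfg.mode is AugmentationMode.NONE:
        return list(records)
    rng = np.random.default_rng(cfg.seed)
    out: list[SubjectRecord] = []
    for rec in records:
        if cfg.mode in (AugmentationMode.BLUR, AugmentationMode.COMBINED):
            out.append(rec.with_volume(gaussian_blur(rec.volume, cfg.blur_sigma)))
        if cfg.mode in (AugmentationMode.ZOOM, AugmentationMode.COMBINED):
            out.append(rec.with_volume(random_zoom(rec.volume, cfg.zoom_scales, rng)))
    return out
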
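"""Zero-center normalization and the spatial / DCT-frequency input representations.

The network consumes either the raw volume (spatial domain) or its full 3D
DCT-II coefficient grid (frequency domain); in both cases the representation is
z-scored over all voxels before entering the input layer.  The DCT is the
separable orthonormal type-II transform, so it is exactly invertible and
energy-preserving (Parseval).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy import fft as _fft

__all__ = ["Domain", "zero_center", "dct3", "idct3", "to_model_input", "DegenerateVolumeError"]


class Domain(str, Enum):
    SPATIAL = "spatial"
    FREQUENCY = "frequency"


class DegenerateVolumeError(ValueError):
    """Raised for constant (zero-variance) or non-finite volumes."""


def zero_center(v: np.ndarray) -> np.ndarray:
    """Z-score a volume over all voxels: subtract the mean, divide by the
    standard deviation.  Output has mean 0 and sd 1 to within 1e-6."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise DegenerateVolumeError("volume contains non-finite intensities")
    sd = v.std()
    if sd == 0:
        raise DegenerateVolumeError("constant volume has zero variance")
    return (v - v.mean()) / sd


def dct3(v: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II applied independently along each of the three axes."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise DegenerateVolumeError("volume contains non-finite intensities")
    return _fft.dctn(v, type=2, norm="ortho")


def idct3(c: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`dct3` (orthonormal DCT-III along each axis)."""
    c = np.asarray(c, dtype=np.float64)
    if not np.all(np.isfinite(c)):
        raise DegenerateVolumeError("coefficients contain non-finite values")
    return _fft.idctn(c, type=2, norm="ortho")


def to_model_input(v: np.ndarray, domain: Domain | str) -> np.ndarray:
    """Representation fed to the network: ``zero_center(v)`` in the spatial
    domain, ``zero_center(dct3(v))`` in the frequency domain.  Shape unchanged."""
    domain = Domain(domain)
    if domain is Domain.SPATIAL:
        return zero_center(v)
    return zero_center(dct3(v))
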
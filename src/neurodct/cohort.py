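"""Synthetic PET/SPECT-like cohort generation and NIfTI round-trip I/O.

Real AD/PD neuroimaging cohorts (ADNI PET, PPMI SPECT) are access-restricted,
so every downstream stage of the pipeline is exercised on synthetic volumes
with a known, controllable class signal: a smooth ellipsoidal "brain" template
on a fixed voxel grid, class-specific regional hypo-intensity (a
medial-temporal-like block for AD, a striatal-like block for PD), a per-subject
global offset, and i.i.d. voxelwise Gaussian noise.  The geometry is defined in
fractional coordinates so the same signal is present at any grid size.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

DEFAULT_SHAPE: tuple[int, int, int] = (79, 95, 69)

__all__ = [
    "DEFAULT_SHAPE",
    "ClassLabel",
    "Modality",
    "Split",
    "CohortSpec",
    "SubjectRecord",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "brain_template",
    "class_effect_mask",
    "centroid_classifier_accuracy",
    "CohortError",
    "CohortIOError",
]


class ClassLabel(str, Enum):
    """Diagnostic group; NC is duplicated per modality because the two
    classification tasks use different normal-control cohorts."""

    AD = "AD"
    NC_PET = "NC_PET"
    NC_SPECT = "NC_SPECT"
    PD = "PD"

    @property
    def modality(self) -> "Modality":
        if self in (ClassLabel.AD, ClassLabel.NC_PET):
            return Modality.PET
        return Modality.SPECT


class Modality(str, Enum):
    PET = "PET"
    SPECT = "SPECT"


class Split(str, Enum):
    TRAIN = "train"
    VALIDATION = "validation"
    TEST = "test"
    UNASSIGNED = "unassigned"


class CohortError(ValueError):
    """Invalid cohort parameters."""


class CohortIOError(IOError):
    """Manifest/file mismatch or unreadable cohort directory."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_per_class:
        Number of subjects in each of the four groups (AD, NC_PET, NC_SPECT, PD).
    effect_size:
        Amplitude (in template intensity units) of the regional class signal.
        ``effect_size = 0`` makes the class-conditional distributions identical
        within a modality.
    noise_sd:
        Standard deviation of the i.i.d. voxelwise Gaussian noise.
    subject_sd:
        Standard deviation of the per-subject global intensity offset.
    seed:
        Master seed; the cohort is a pure function of this spec.
    shape:
        Voxel grid, default the pipeline-entry grid (79, 95, 69).
    """

    n_per_class: int
    effect_size: float = 2.5
    noise_sd: float = 0.5
    subject_sd: float = 0.2
    seed: int = 0
    shape: tuple[int, int, int] = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise CohortError(f"n_per_class must be positive, got {self.n_per_class}")
        if self.noise_sd <= 0:
            raise CohortError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.effect_size < 0:
            raise CohortError(f"effect_size must be non-negative, got {self.effect_size}")
        if self.subject_sd < 0:
            raise CohortError(f"subject_sd must be non-negative, got {self.subject_sd}")
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise CohortError(f"shape must be 3 axes of at least 8 voxels, got {self.shape}")


@dataclass
class SubjectRecord:
    """One subject: identifier, diagnostic label, modality, volume, split."""

    subject_id: str
    label: ClassLabel
    modality: Modality
    volume: np.ndarray
    split: Split = Split.UNASSIGNED

    def __post_init__(self) -> None:
        if self.label.modality is not self.modality:
            raise CohortError(
                f"label {self.label.value} implies modality {self.label.modality.value}, "
                f"got {self.modality.value}"
            )

    def with_volume(self, volume: np.ndarray) -> "SubjectRecord":
        return SubjectRecord(self.subject_id, self.label, self.modality, volume, self.split)

    def with_split(self, split: Split) -> "SubjectRecord":
        return SubjectRecord(self.subject_id, self.label, self.modality, self.volume, split)


# ---------------------------------------------------------------------------
# template geometry (fractional coordinates, so any grid size carries the
# same signal)
# ---------------------------------------------------------------------------

# axis-aligned fractional sub-blocks standing in for the affected anatomy
_AD_BLOCK = ((0.28, 0.50), (0.30, 0.55), (0.25, 0.45))  # medial-temporal-like
_PD_BLOCK = ((0.38, 0.62), (0.42, 0.62), (0.40, 0.60))  # striatal-like

# PET and SPECT volumes differ by a fixed global intensity gain (tracer /
# detector count scales are arbitrary and modality-specific); the gain
# multiplies the complete measured volume — template, regional effect,
# subject offset and noise alike — so per-volume zero-centering removes it
_MODALITY_GAIN = {
    Modality.PET: 1.0,
    Modality.SPECT: 0.8,
}

_TEMPLATE_CONTRAST = 4.0  # peak uptake, template units
_TEMPLATE_FALLOFF = 2.0


def _normalized_grid(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def brain_mask(shape: tuple[int, int, int] = DEFAULT_SHAPE) -> np.ndarray:
    """Boolean ellipsoidal mask (semi-axes 0.9 of each half-extent)."""
    gx, gy, gz = _normalized_grid(shape)
    r2 = (gx / 0.9) ** 2 + (gy / 0.9) ** 2 + (gz / 0.9) ** 2
    return r2 <= 1.0


def _base_template(shape: tuple[int, int, int]) -> np.ndarray:
    gx, gy, gz = _normalized_grid(shape)
    r2 = (gx / 0.9) ** 2 + (gy / 0.9) ** 2 + (gz / 0.9) ** 2
    template = _TEMPLATE_CONTRAST * np.exp(-_TEMPLATE_FALLOFF * r2)
    template[r2 > 1.0] = 0.0
    return template


def brain_template(
    modality: Modality, shape: tuple[int, int, int] = DEFAULT_SHAPE
) -> np.ndarray:
    """Smooth ellipsoidal uptake template; exactly 0 outside the brain mask."""
    return _MODALITY_GAIN[modality] * _base_template(shape)


def class_effect_mask(label: ClassLabel, shape: tuple[int, int, int] = DEFAULT_SHAPE) -> np.ndarray:
    """Boolean mask of the class-affected sub-block (all-False for NC)."""
    if label is ClassLabel.AD:
        block = _AD_BLOCK
    elif label is ClassLabel.PD:
        block = _PD_BLOCK
    else:
        return np.zeros(shape, dtype=bool)
    mask = np.ones(shape, dtype=bool)
    for axis, (lo, hi) in enumerate(block):
        n = shape[axis]
        idx = np.zeros(n, dtype=bool)
        idx[int(round(lo * n)) : int(round(hi * n))] = True
        mask &= np.expand_dims(idx, tuple(a for a in range(3) if a != axis))
    return mask


def class_template(label: ClassLabel, spec: CohortSpec) -> np.ndarray:
    """Noise-free expected volume of a class: template minus the regional
    hypo-intensity of magnitude ``effect_size`` (template units), all scaled
    by the modality gain."""
    template = _base_template(spec.shape)
    effect = class_effect_mask(label, spec.shape)
    out = template.copy()
    out[effect & brain_mask(spec.shape)] -= spec.effect_size
    return _MODALITY_GAIN[label.modality] * out


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # stable per-subject stream: hash (seed, index) into a SeedSequence
    digest = hashlib.sha256(f"{seed}:{index}".encode()).digest()
    entropy = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate ``4 * n_per_class`` labeled subjects, fully determined by the spec.

    Each volume is ``class_template + Normal(0, subject_sd^2)`` (global, masked)
    ``+ Normal(0, noise_sd^2)`` (voxelwise, masked); background stays exactly 0.
    """
    mask = brain_mask(spec.shape)
    records: list[SubjectRecord] = []
    index = 0
    for label in ClassLabel:
        base = class_template(label, spec)
        gain = _MODALITY_GAIN[label.modality]
        for k in range(spec.n_per_class):
            rng = _subject_rng(spec.seed, index)
            volume = base.copy()
            offset = rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
            volume[mask] += gain * offset
            volume[mask] += gain * rng.normal(0.0, spec.noise_sd, size=int(mask.sum()))
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{label.value}-{k:04d}",
                    label=label,
                    modality=label.modality,
                    volume=volume,
                )
            )
            index += 1
    return records


# ---------------------------------------------------------------------------
# I/O: one NIfTI-1 file per subject + CSV manifest
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"
_STORAGE_DTYPE = np.float32

#: worst-case absolute round-trip error of float32 storage for a value of
#: magnitude ``m`` is ``m * 2**-24`` (half-ulp); exposed for tests
STORAGE_REL_EPS = 2.0 ** -23


def write_cohort(records: list[SubjectRecord], directory: str | Path) -> Path:
    """Write one ``.nii.gz`` per subject plus a CSV manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        filename = f"{rec.subject_id}.nii.gz"
        img = nib.Nifti1Image(rec.volume.astype(_STORAGE_DTYPE), affine=np.eye(4))
        nib.save(img, directory / filename)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label.value,
                "modality": rec.modality.value,
                "filename": filename,
            }
        )
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=["subject_id", "label", "modality", "filename"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort`; errors name the
    offending subject."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise CohortIOError(f"no manifest at {manifest}")
    table = pd.read_csv(manifest, dtype=str)
    records = []
    for row in table.itertuples(index=False):
        path = directory / row.filename
        if not path.exists():
            raise CohortIOError(
                f"manifest entry for subject {row.subject_id!r} points to missing file {row.filename}"
            )
        volume = np.asanyarray(nib.load(path).dataobj, dtype=np.float64)
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                label=ClassLabel(row.label),
                modality=Modality(row.modality),
                volume=volume,
            )
        )
    return records


# ---------------------------------------------------------------------------
# simple reference classifier used to calibrate class separation
# ---------------------------------------------------------------------------

def centroid_classifier_accuracy(
    train: list[SubjectRecord], test: list[SubjectRecord]
) -> float:
    """Accuracy of a nearest-class-centroid classifier on zero-centered
    volumes (the pipeline-entry representation).  Used as a cheap
    separability oracle for cohorts."""

    def z(v: np.ndarray) -> np.ndarray:
        flat = v.ravel()
        return (flat - flat.mean()) / flat.std()

    labels = sorted({r.label for r in train}, key=lambda l: l.value)
    centroids = np.stack(
        [
            np.mean([z(r.volume) for r in train if r.label is lab], axis=0)
            for lab in labels
        ]
    )
    correct = 0
    for rec in test:
        d = np.linalg.norm(centroids - z(rec.volume)[None, :], axis=1)
        if labels[int(np.argmin(d))] is rec.label:
            correct += 1
    return correct / len(test)
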
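"""Voxel-wise NGTDM texture extraction from PET lesion volumes.

The scheme: quantize the volume with equal-width bins spanning the SUV
range inside the lesion mask (128 bins by default), cut a 5x5x5
sub-volume around every lesion voxel, compute each NGTDM feature on the
central axial, coronal and sagittal plane of that cube, average the
three plane values to get the voxel's feature, and average over all
lesion voxels to get the lesion's feature.

Axes are ordered (axial slice, row, column), 0-based: the axial plane
fixes the slice index, the coronal plane fixes the row, the sagittal
plane fixes the column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .ngtdm import (
    DEFAULT_EPSILON,
    EmptyNgtdmError,
    QuantizedPatch,
    TextureTriplet,
    build_ngtdm,
    texture_triplet,
)

__all__ = [
    "PetVolume",
    "LesionMask",
    "TextureConfig",
    "LesionFeatures",
    "quantize_lesion",
    "extract_subvolume",
    "voxel_features",
    "lesion_features",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
]

TIMEPOINTS = ("early", "delayed")


@dataclass(frozen=True)
class PetVolume:
    """A 3-D PET image in SUV units (g/ml) with voxel spacing in mm and a
    time-point tag (``early`` ~1 h or ``delayed`` ~3 h post-injection)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (4.25, 4.25, 4.25)
    timepoint: str = "early"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError("PET volume must be 3-D")
        if not np.isfinite(data).all():
            raise ValueError("PET volume contains non-finite intensities")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion segmentation on the same grid as its volume."""

    member: np.ndarray

    def __post_init__(self) -> None:
        member = np.asarray(self.member, dtype=bool)
        if member.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not member.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "member", member)

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())


@dataclass(frozen=True)
class TextureConfig:
    """Extraction settings.

    ``n_bins``: gray tones for lesion-range quantization (default 128).
    ``subvolume_size``: odd cube edge around each voxel (default 5).
    ``policy``: NGTDM pixel-eligibility policy.
    ``epsilon``: coarseness regularizer (1/epsilon is the uniform cap).
    ``all_slices``: if True, features are averaged over every slice of
    the cube in each orientation instead of the single central plane.
    """

    n_bins: int = 128
    subvolume_size: int = 5
    distance: int = 1
    policy: str = "strict-interior"
    epsilon: float = DEFAULT_EPSILON
    all_slices: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.subvolume_size < 3 or self.subvolume_size % 2 == 0:
            raise ValueError("subvolume_size must be an odd integer >= 3")


@dataclass(frozen=True)
class LesionFeatures:
    """Per-lesion texture averages plus simple uptake metrics."""

    triplet: TextureTriplet
    suvmax: float
    n_voxels: int
    n_undefined: int


def quantize_lesion(
    volume: PetVolume, mask: LesionMask, n_bins: int = 128
) -> np.ndarray:
    """Equal-width quantization of the whole volume using the SUV range
    inside the lesion mask.

    Bin edges partition ``[min, max]`` of the in-mask intensities into
    ``n_bins`` equal widths; indices run 1..n_bins with the in-mask
    maximum mapping to bin ``n_bins``.  Out-of-mask voxels (which can
    enter extracted sub-volumes) are binned with the same lesion-derived
    edges and clamped to [1, n_bins].
    """
    if mask.member.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume shape")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    inside = volume.data[mask.member]
    lo = float(inside.min())
    hi = float(inside.max())
    if hi <= lo:
        warnings.warn("constant lesion intensity: all voxels map to bin 1")
        return np.ones(volume.data.shape, dtype=np.int32)
    scaled = (volume.data.astype(np.float64) - lo) / (hi - lo)
    binned = np.floor(scaled * n_bins).astype(np.int32) + 1
    np.clip(binned, 1, n_bins, out=binned)
    return binned


def extract_subvolume(
    binned: np.ndarray, center: tuple[int, int, int], size: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """The ``size``^3 cube of bin indices centered on a voxel.

    Returns ``(values, valid)``: cells beyond the image boundary carry
    ``valid=False`` and a placeholder value of 1 — no padding intensity
    is invented.
    """
    if size < 3 or size % 2 == 0:
        raise ValueError("size must be an odd integer >= 3")
    half = size // 2
    shape = binned.shape
    if any(not (0 <= c < s) for c, s in zip(center, shape)):
        raise ValueError(f"center {center} outside image of shape {shape}")
    values = np.ones((size, size, size), dtype=binned.dtype)
    valid = np.zeros((size, size, size), dtype=bool)
    src = []
    dst = []
    for c, s in zip(center, shape):
        lo = max(c - half, 0)
        hi = min(c + half + 1, s)
        src.append(slice(lo, hi))
        dst.append(slice(lo - (c - half), hi - (c - half)))
    values[tuple(dst)] = binned[tuple(src)]
    valid[tuple(dst)] = True
    return values, valid


def _cube_planes(
    values: np.ndarray, valid: np.ndarray, all_slices: bool
) -> list[tuple[np.ndarray, np.ndarray]]:
    size = values.shape[0]
    c = size // 2
    idx = range(size) if all_slices else (c,)
    planes: list[tuple[np.ndarray, np.ndarray]] = []
    for i in idx:
        planes.append((values[i, :, :], valid[i, :, :]))   # axial
    for i in idx:
        planes.append((values[:, i, :], valid[:, i, :]))   # coronal
    for i in idx:
        planes.append((values[:, :, i], valid[:, :, i]))   # sagittal
    return planes


def voxel_features(
    values: np.ndarray,
    valid: np.ndarray,
    config: TextureConfig = TextureConfig(),
) -> TextureTriplet | None:
    """NGTDM features of one voxel's sub-volume: each feature computed
    per directional plane, then averaged over the planes that produced a
    defined value.  Returns None when every plane is ineligible (the
    voxel is excluded from the lesion average and counted)."""
    triplets: list[TextureTriplet] = []
    for pv, pm in _cube_planes(values, valid, config.all_slices):
        if not pm.any():
            continue
        try:
            table = build_ngtdm(
                QuantizedPatch(pv, pm), distance=config.distance, policy=config.policy
            )
        except EmptyNgtdmError:
            continue
        triplets.append(texture_triplet(table, config.epsilon))
    if not triplets:
        return None
    stack = np.array([t.as_array() for t in triplets])
    mean = stack.mean(axis=0)
    return TextureTriplet(*mean)


def lesion_features(
    volume: PetVolume,
    mask: LesionMask,
    config: TextureConfig = TextureConfig(),
) -> LesionFeatures:
    """Lesion-level features: the arithmetic mean of defined per-voxel
    triplets, plus SUVmax inside the mask and the metabolic volume
    (mask voxel count)."""
    if mask.member.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume shape")
    binned = quantize_lesion(volume, mask, config.n_bins)
    size = config.subvolume_size
    half = size // 2
    # Padded copies make every sub-volume a constant-time slice.
    pad = [(half, half)] * 3
    padded_vals = np.pad(binned, pad, constant_values=1)
    padded_valid = np.pad(np.ones(binned.shape, dtype=bool), pad, constant_values=False)

    sums = np.zeros(3)
    n_defined = 0
    n_undefined = 0
    for z, y, x in np.argwhere(mask.member):
        values = padded_vals[z : z + size, y : y + size, x : x + size]
        valid = padded_valid[z : z + size, y : y + size, x : x + size]
        triplet = voxel_features(values, valid, config)
        if triplet is None:
            n_undefined += 1
            continue
        sums += triplet.as_array()
        n_defined += 1
    if n_defined == 0:
        raise ValueError("every lesion voxel has undefined texture")
    mean = sums / n_defined
    return LesionFeatures(
        triplet=TextureTriplet(*mean),
        suvmax=float(volume.data[mask.member].max()),
        n_voxels=mask.n_voxels,
        n_undefined=n_undefined,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: PetVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing))
    nib.save(img, str(path))


def load_volume(path: str | Path, timepoint: str) -> PetVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PetVolume(data=data, spacing=spacing, timepoint=timepoint)


def save_mask(mask: LesionMask, spacing: tuple[float, float, float], path: str | Path) -> None:
    img = nib.Nifti1Image(mask.member.astype(np.uint8), _affine(spacing))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> LesionMask:
    img = nib.load(str(path))
    return LesionMask(member=np.asarray(img.dataobj) > 0)
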
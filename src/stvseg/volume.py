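"""Volume data model, I/O, ROI cropping, transverse reslicing and re-stacking.

All grids use index order ``(z, y, x)`` with 0-based indices and half-open
bounds; spacing and origin tuples follow the same order, in millimetres.
3D ultrasound acquisitions of the thumb base are strongly anisotropic: the
native transverse planes are finely sampled in-plane (~0.114 mm) while the
probe-sweep direction is coarser (~0.333 mm), so all slice operations work
on native transverse planes and never interpolate across slices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "UltrasoundVolume",
    "LabelVolume",
    "RegionOfInterest",
    "SliceStack",
    "DEFAULT_SPACING",
    "load_volume",
    "save_volume",
    "load_label",
    "save_label",
    "roi_from_label",
    "crop",
    "reslice",
    "restack",
    "split_by_volume",
]

#: Native voxel spacing of the mechanically swept 3D probe, (dz, dy, dx) mm.
DEFAULT_SPACING = (0.333, 0.114, 0.114)


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a 3D scalar volume."""


@dataclass(frozen=True)
class UltrasoundVolume:
    """3D greyscale ultrasound volume with anisotropic voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensities normalised to [0, 1].
    spacing : tuple of float
        Voxel size ``(dz, dy, dx)`` in mm; strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0), ``(z0, y0, x0)`` in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"voxels must be a 3D grid, got shape {v.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if float(v.min()) < -1e-9 or float(v.max()) > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]; normalise at load time")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass(frozen=True)
class LabelVolume:
    """Binary voxel-wise membership of the synovial region.

    Shape and spacing must match the paired :class:`UltrasoundVolume`.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"voxels must be a 3D grid, got shape {v.shape}")
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("label values must be in {0, 1}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "voxels", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_mm3(self) -> float:
        """Foreground volume by voxel counting."""
        dz, dy, dx = self.spacing
        return float(self.voxels.sum()) * dz * dy * dx


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open voxel index bounds ``[lo, hi)`` per axis, (z, y, x) order."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if any(l < 0 for l in lo) or any(l >= h for l, h in zip(lo, hi)):
            raise ValueError(f"require 0 <= lo < hi per axis, got lo={lo}, hi={hi}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


@dataclass(frozen=True)
class SliceStack:
    """Ordered transverse 2D slices sampled from a parent volume."""

    images: list  # list of 2D float arrays, shared shape
    slice_indices: tuple  # z index of each image in the parent volume
    in_plane_spacing: tuple[float, float]  # (dy, dx) mm
    slice_spacing: float = DEFAULT_SPACING[0]  # dz mm of the parent
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.slice_indices)
        if len(self.images) != len(idx):
            raise ValueError("one slice index per image required")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("slice_indices must be strictly increasing")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"all slices must share one shape, got {shapes}")
        object.__setattr__(self, "slice_indices", idx)

    def __len__(self) -> int:
        return len(self.images)

    def z_positions_mm(self) -> np.ndarray:
        """Physical z of every slice."""
        return self.origin[0] + np.asarray(self.slice_indices) * self.slice_spacing


# ---------------------------------------------------------------------------
# I/O

def _read_image(path: str) -> sitk.Image:
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on bad files
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D volume, got {img.GetDimension()}D payload"
        )
    return img


def load_volume(path: str) -> UltrasoundVolume:
    """Read a NIfTI/MetaImage volume; intensities are min-max normalised to [0, 1].

    Spacing and origin come from the header (SimpleITK's (x, y, z) order is
    reversed into this package's (z, y, x) convention).
    """
    img = _read_image(path)
    arr = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    lo, hi = float(arr.min()), float(arr.max())
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return UltrasoundVolume(
        voxels=arr,
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )


def load_label(path: str) -> LabelVolume:
    """Read a binary label volume; any value > 0.5 counts as foreground."""
    img = _read_image(path)
    arr = (sitk.GetArrayFromImage(img) > 0.5).astype(np.uint8)
    return LabelVolume(
        voxels=arr,
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
    )


def _write(arr: np.ndarray, spacing, origin, path: str) -> None:
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(spacing)))
    img.SetOrigin(tuple(reversed(origin)))
    sitk.WriteImage(img, str(path))


def save_volume(volume: UltrasoundVolume, path: str) -> None:
    _write(volume.voxels.astype(np.float32), volume.spacing, volume.origin, path)


def save_label(label: LabelVolume, path: str) -> None:
    _write(label.voxels.astype(np.uint8), label.spacing, label.origin, path)


# ---------------------------------------------------------------------------
# ROI and slicing

def roi_from_label(label: LabelVolume, margin_voxels: int = 15) -> RegionOfInterest:
    """Tight foreground bounding box expanded by ``margin_voxels`` per side.

    Emulates the manually drawn region of interest around the joint: a
    boundary of roughly 15 voxels beyond the segmented structure in every
    direction, clamped to the volume bounds.
    """
    if margin_voxels < 0:
        raise ValueError("margin must be >= 0")
    fg = np.argwhere(label.voxels > 0)
    if fg.size == 0:
        raise ValueError("label volume contains no foreground voxels")
    lo = np.maximum(fg.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(fg.max(axis=0) + 1 + margin_voxels, label.shape)
    return RegionOfInterest(lo=tuple(lo), hi=tuple(hi))


def crop(volume, roi: RegionOfInterest):
    """Crop a volume or label to ``roi``; origin shifts by ``lo * spacing``."""
    if any(h > s for h, s in zip(roi.hi, volume.shape)):
        raise IndexError(f"roi {roi} exceeds volume shape {volume.shape}")
    sub = volume.voxels[roi.slices()]
    origin = tuple(o + l * s for o, l, s in zip(volume.origin, roi.lo, volume.spacing))
    cls = type(volume)
    return cls(voxels=sub.copy(), spacing=volume.spacing, origin=origin)


def _even_indices(depth: int, n_slices: int) -> np.ndarray:
    # evenly spaced integer z spanning [0, depth-1], endpoints included
    if n_slices == 1:
        return np.array([0])
    return np.round(np.arange(n_slices) * (depth - 1) / (n_slices - 1)).astype(int)


def reslice(volume: UltrasoundVolume, n_slices: int) -> SliceStack:
    """Sample ``n_slices`` native transverse planes at evenly spaced z indices.

    No interpolation is performed: each slice is the native plane, so paired
    label slices stay binary. First and last planes are always included.
    """
    depth = volume.shape[0]
    if not 1 <= n_slices <= depth:
        raise ValueError(f"n_slices must be in [1, {depth}], got {n_slices}")
    idx = _even_indices(depth, n_slices)
    return SliceStack(
        images=[volume.voxels[z].copy() for z in idx],
        slice_indices=tuple(idx),
        in_plane_spacing=(volume.spacing[1], volume.spacing[2]),
        slice_spacing=volume.spacing[0],
        origin=volume.origin,
    )


def reslice_label(label: LabelVolume, n_slices: int) -> SliceStack:
    """Same plane sampling as :func:`reslice`, for a label volume."""
    depth = label.shape[0]
    if not 1 <= n_slices <= depth:
        raise ValueError(f"n_slices must be in [1, {depth}], got {n_slices}")
    idx = _even_indices(depth, n_slices)
    return SliceStack(
        images=[label.voxels[z].copy() for z in idx],
        slice_indices=tuple(idx),
        in_plane_spacing=(label.spacing[1], label.spacing[2]),
        slice_spacing=label.spacing[0],
        origin=label.origin,
    )


def restack(
    stack: SliceStack,
    masks: Sequence[np.ndarray],
    parent_shape: tuple[int, int, int],
) -> LabelVolume:
    """Place 2D binary masks back into a 3D label volume at known z locations.

    The result is zero everywhere except at the stack's slice indices.
    """
    if len(masks) != len(stack):
        raise ValueError(f"need {len(stack)} masks, got {len(masks)}")
    out = np.zeros(parent_shape, dtype=np.uint8)
    for z, m in zip(stack.slice_indices, masks):
        m = np.asarray(m)
        if m.shape != parent_shape[1:]:
            raise ValueError(
                f"mask shape {m.shape} does not match plane shape {parent_shape[1:]}"
            )
        out[z] = (m > 0.5).astype(np.uint8)
    dz = stack.slice_spacing
    dy, dx = stack.in_plane_spacing
    return LabelVolume(voxels=out, spacing=(dz, dy, dx), origin=stack.origin)


def split_by_volume(
    volume_ids: Sequence, train_fraction: float, seed: int
) -> tuple[list, list]:
    """Seeded train/test partition at the 3D-volume level.

    Splitting whole volumes (never individual slices) guarantees that no
    slice of a test volume leaks into training. Train size is
    ``round(train_fraction * n)``.
    """
    ids = list(volume_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 volume ids to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)  # both sets nonempty
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test
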
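"""Reading, writing and validating intensity volumes with VOI masks.

Volumes and masks are NIfTI-1 images on the same grid. All downstream
analysis is grid-based: the affine is preserved on write but never used in
computation, and voxel spacing (mm) is carried along purely as metadata
because co-occurrence offsets are measured in voxels, not millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeWithMask",
    "VoxelSet",
    "GeometryError",
    "EmptyVOIError",
    "read_volume_with_mask",
    "write_volume_with_mask",
    "extract_voi",
]

GROUP_LABELS = ("AB", "OKC")


class GeometryError(ValueError):
    """Volume and mask grids do not agree."""


class EmptyVOIError(ValueError):
    """The VOI mask selects no voxels."""


@dataclass
class VolumeWithMask:
    """An intensity volume, its voxel spacing and an aligned binary VOI mask.

    Parameters
    ----------
    intensities
        3-D scalar field (arbitrary real units; MRI intensities are not
        calibrated).
    spacing
        Voxel edge lengths in mm per axis, all strictly positive.
    mask
        Boolean field on the same grid; must contain at least one foreground
        voxel.
    subject_id
        Opaque identifier.
    group_label
        ``"AB"``, ``"OKC"`` or ``None`` for unlabeled volumes.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray
    subject_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise GeometryError(
                f"expected a 3-D volume, got shape {self.intensities.shape}"
            )
        if self.intensities.shape != self.mask.shape:
            raise GeometryError(
                "volume and mask grids differ: "
                f"{self.intensities.shape} vs {self.mask.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not self.mask.any():
            raise EmptyVOIError(
                f"mask selects no voxels (subject {self.subject_id!r})"
            )
        if self.group_label is not None and self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"group_label must be one of {GROUP_LABELS} or None, "
                f"got {self.group_label!r}"
            )

    @property
    def n_voi_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VoxelSet:
    """The segmented VOI voxels: 0-based grid indices and matched intensities.

    Coordinates are unique and ordered raster-style (z-major, then y, then x)
    so that every downstream computation is deterministic.
    """

    coordinates: np.ndarray  # (n, 3) int
    values: np.ndarray  # (n,)
    grid_shape: tuple[int, int, int] = field(default=(0, 0, 0))

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.intp)
        self.values = np.asarray(self.values)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n, 3)")
        if len(self.coordinates) != len(self.values):
            raise ValueError("coordinates and values length mismatch")
        if len(np.unique(self.coordinates, axis=0)) != len(self.coordinates):
            raise ValueError("coordinates must be unique")

    def __len__(self) -> int:
        return len(self.values)


def read_volume_with_mask(
    volume_path: str | Path,
    mask_path: str | Path,
    subject_id: str | None = None,
    group_label: str | None = None,
) -> VolumeWithMask:
    """Load a NIfTI volume and its VOI mask from disk and validate them.

    The mask is binarized as ``value > 0`` so that label-map exports (where
    the lesion may carry label 2, 3, ...) are tolerated. Raises
    :class:`GeometryError` on grid mismatch, :class:`EmptyVOIError` on an
    all-zero mask and ``FileNotFoundError``/``nibabel`` errors for unreadable
    files.
    """
    volume_path = Path(volume_path)
    mask_path = Path(mask_path)
    vol_img = nib.load(volume_path)
    mask_img = nib.load(mask_path)
    intensities = np.asanyarray(vol_img.dataobj)
    mask = np.asanyarray(mask_img.dataobj) > 0
    if intensities.shape != mask.shape:
        raise GeometryError(
            f"volume {volume_path.name} has shape {intensities.shape} but mask "
            f"{mask_path.name} has shape {mask.shape}"
        )
    spacing = tuple(float(z) for z in vol_img.header.get_zooms()[:3])
    if subject_id is None:
        subject_id = volume_path.name.removesuffix(".gz").removesuffix(".nii")
    return VolumeWithMask(
        intensities=intensities,
        spacing=spacing,
        mask=mask,
        subject_id=subject_id,
        group_label=group_label,
    )


def write_volume_with_mask(
    vwm: VolumeWithMask, volume_path: str | Path, mask_path: str | Path
) -> None:
    """Write the volume and mask as NIfTI-1 with a diagonal spacing affine."""
    affine = np.diag((*vwm.spacing, 1.0))
    nib.save(nib.Nifti1Image(vwm.intensities, affine), str(volume_path))
    nib.save(
        nib.Nifti1Image(vwm.mask.astype(np.uint8), affine), str(mask_path)
    )


def extract_voi(vwm: VolumeWithMask) -> VoxelSet:
    """Return exactly the foreground voxels with their 0-based grid indices.

    Order is raster (z-major, then y, then x).
    """
    idx = np.argwhere(vwm.mask)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))
    idx = idx[order]
    values = vwm.intensities[idx[:, 0], idx[:, 1], idx[:, 2]]
    return VoxelSet(coordinates=idx, values=values, grid_shape=vwm.mask.shape)
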
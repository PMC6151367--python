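"""3D activity volumes: the in-memory image container and NIfTI-1 I/O.

An :class:`ActivityVolume` is a plain 3D scalar grid of radiotracer activity
concentration (MBq/cc) with voxel spacing and a world-space origin.  Every
stage of the pipeline (simulation, segmentation, feature extraction) consumes
and produces these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ActivityVolume:
    """A 3D scalar image with geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Activity concentration per voxel, MBq/cc.  Non-negative.
    spacing : tuple of float
        Voxel edge lengths (x, y, z) in mm, strictly positive.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (1 cc = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def total_activity(self) -> float:
        """Integral of the concentration field, MBq."""
        return float(self.values.sum()) * self.voxel_volume_cc

    def copy(self) -> "ActivityVolume":
        return replace(self, values=self.values.copy(), meta=dict(self.meta))

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge lengths of the imaged box in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


def resample_to_spacing(
    vol: ActivityVolume,
    new_spacing: tuple[float, float, float],
    order: int = 1,
) -> ActivityVolume:
    """Resample a volume onto a grid with different voxel spacing.

    The physical field of view is preserved (up to one voxel at the edges)
    and the two grids are aligned on the volume center, so the integral of a
    smooth field is conserved.  ``order=1`` is trilinear (images), ``order=0``
    nearest-neighbour (masks / label maps).
    """
    new_spacing = tuple(float(s) for s in new_spacing)
    if any(s <= 0 for s in new_spacing):
        raise ValueError("new spacing must be positive")
    old_shape = np.array(vol.shape, dtype=float)
    old_sp = np.array(vol.spacing)
    new_sp = np.array(new_spacing)
    new_shape = np.maximum(1, np.round(old_shape * old_sp / new_sp)).astype(int)

    # voxel-center alignment: world(i_new) = world(i_old) with grids sharing
    # the same physical center
    centers_old = (old_shape - 1) / 2.0
    centers_new = (new_shape - 1) / 2.0
    grids = np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij")
    coords = [
        (g - cn) * ns / os + co
        for g, cn, ns, os, co in zip(grids, centers_new, new_sp, old_sp, centers_old)
    ]
    out = ndimage.map_coordinates(
        vol.values, np.stack(coords), order=order, mode="nearest"
    )
    origin = tuple(
        o + (co - cn * ns / os) * os
        for o, co, cn, ns, os in zip(
            vol.origin, centers_old, centers_new, new_sp, old_sp
        )
    )
    return ActivityVolume(np.clip(out, 0, None), new_spacing, origin, dict(vol.meta))


def write_volume(vol: ActivityVolume, path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), spacing in the header."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path) -> ActivityVolume:
    """Read a 3D NIfTI-1 volume; rejects non-3D images and missing spacing."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"invalid voxel spacing in header: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ActivityVolume(np.clip(data, 0, None), tuple(float(z) for z in zooms), origin)
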
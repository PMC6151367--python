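"""Preprocessing before texture analysis: isotropic resampling and
gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import ActivityVolume, resample_to_spacing


def resample_isotropic(
    image: ActivityVolume, mask: np.ndarray
) -> tuple[ActivityVolume, np.ndarray]:
    """Resample image and mask onto an isotropic grid.

    The target spacing is the in-plane (axial-slice) pixel size applied to
    all three axes; the image is interpolated trilinearly, the mask with
    nearest neighbour.  Already-isotropic inputs are returned unchanged.
    """
    sx, sy, sz = image.spacing
    if not np.isclose(sx, sy, rtol=1e-6):
        raise ValueError(f"in-plane spacing must be square, got ({sx}, {sy})")
    ratio = max(image.spacing) / min(image.spacing)
    if ratio > 10:
        raise ValueError(f"anisotropy ratio {ratio:.1f} > 10: unphysical input")
    if np.isclose(sz, sx, rtol=1e-6):
        return image, np.asarray(mask, dtype=bool)
    target = (sx, sx, sx)
    img_iso = resample_to_spacing(image, target, order=1)
    mask_vol = ActivityVolume(
        np.asarray(mask, dtype=float), image.spacing, image.origin
    )
    mask_iso = resample_to_spacing(mask_vol, target, order=0).values > 0.5
    return img_iso, mask_iso


@dataclass
class DiscretizedVolume:
    """Gray levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray
    n_levels: int
    original_range: tuple[float, float]
    degenerate: bool = False  # constant region mapped wholly to level 1

    def __post_init__(self):
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("levels out of range inside mask")

    def cropped(self) -> "DiscretizedVolume":
        """Restrict to the mask bounding box (texture matrices are local)."""
        idx = np.argwhere(self.mask)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        return DiscretizedVolume(
            self.levels[sl], self.mask[sl], self.n_levels,
            self.original_range, self.degenerate,
        )


def discretize(
    image: ActivityVolume | np.ndarray, mask: np.ndarray, n_levels: int = 64
) -> DiscretizedVolume:
    """Map within-mask intensities onto 1..n_levels with fixed bin count.

    level(v) = max(1, ceil(n * (v - min) / (max - min))), so the minimum
    maps to 1, the maximum to n, and an arithmetic ramp splits into
    equally-populated bins.  A constant region maps wholly to level 1 and
    is flagged degenerate.
    """
    values = image.values if isinstance(image, ActivityVolume) else np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    inside = values[mask].astype(np.float64)
    vmin, vmax = float(inside.min()), float(inside.max())
    levels = np.zeros(values.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
        return DiscretizedVolume(levels, mask, n_levels, (vmin, vmax), degenerate=True)
    scaled = np.ceil(n_levels * (inside - vmin) / (vmax - vmin))
    levels[mask] = np.clip(scaled, 1, n_levels).astype(np.int32)
    return DiscretizedVolume(levels, mask, n_levels, (vmin, vmax))
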
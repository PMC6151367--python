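"""Irregular lesion shells: star-shaped random solids with known geometry.

Real oncological lesions are not spheres.  We synthesize irregular closed
shapes by radially perturbing a sphere with a band-limited random function on
the unit sphere (a seeded spherical-harmonic expansion), which guarantees a
single connected, star-shaped solid whose surface can be meshed accurately.

The ground-truth sphericity index compares the surface of the
volume-equivalent sphere to the actual surface:

    S = pi^(1/3) * (6 V)^(2/3) / A

with S = 1 for a perfect sphere and smaller values for irregular shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import trimesh
from scipy.special import sph_harm_y
from skimage import measure


@dataclass(frozen=True)
class ShellSpec:
    """Recipe for one irregular shell.

    Attributes
    ----------
    seed : int
        Seeds the harmonic coefficients; same seed -> bit-identical shape.
    base_radius : float
        Radius (mm) of the unperturbed sphere.
    deformation_amplitude : float
        Relative radial perturbation in [0, 1); 0 gives a sphere.
    resolution : float
        Ground-truth rasterization grid step, mm per voxel.
    lmax : int
        Highest spherical-harmonic degree in the perturbation.
    """

    seed: int
    base_radius: float
    deformation_amplitude: float = 0.0
    resolution: float = 1.0
    lmax: int = 8

    def __post_init__(self):
        if not (0.0 <= self.deformation_amplitude < 1.0):
            raise ValueError("deformation_amplitude must be in [0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.base_radius <= 2 * self.resolution:
            raise ValueError(
                f"base_radius {self.base_radius} mm is unresolvable at "
                f"{self.resolution} mm resolution (needs > 2 voxels)"
            )


@dataclass
class Shell:
    """A generated shell: GS rasterization plus its triangulated surface."""

    spec: ShellSpec
    inside: np.ndarray  # bool voxel occupancy on the GS grid
    field: np.ndarray  # signed radial field r(theta,phi) - rho, > 0 inside
    spacing: tuple[float, float, float]
    mesh: trimesh.Trimesh

    @property
    def volume_cc(self) -> float:
        """Mesh-derived volume in cc."""
        return float(abs(self.mesh.volume)) / 1000.0

    @property
    def surface_cm2(self) -> float:
        """Mesh-derived surface in cm^2."""
        return float(self.mesh.area) / 100.0

    @property
    def sphericity(self) -> float:
        return compute_sphericity_gs(self.volume_cc, self.surface_cm2)

    def radial_fraction(self) -> np.ndarray:
        """Per-voxel rho / r(theta,phi): 0 at center, 1 on the surface.

        Useful for carving concentric compartments: because the solid is
        star-shaped, the sub-region {u <= t} holds exactly t^3 of the volume.
        """
        rho, _ = _polar_grids(self.inside.shape, self.spec.resolution)
        rsurf = rho + self.field  # field = r(theta,phi) - rho
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(rsurf > 0, rho / rsurf, 0.0)
        return u


_THETA_GRID = np.linspace(0.0, np.pi, 181)
_PHI_GRID = np.linspace(-np.pi, np.pi, 361)


@lru_cache(maxsize=64)
def _modulation_table(seed: int, lmax: int):
    """Normalized modulation sampled on a dense (theta, phi) grid.

    The random function is band-limited (degree <= lmax), so a 1-degree
    tabulation plus bilinear interpolation reproduces it to well below the
    voxel-level accuracy of the rasterization, at a fraction of the cost of
    evaluating every harmonic per voxel.
    """
    tg, pg = np.meshgrid(_THETA_GRID, _PHI_GRID, indexing="ij")
    rng = np.random.default_rng(seed)
    f = np.zeros_like(tg)
    for ell in range(2, lmax + 1):
        for m in range(0, ell + 1):
            a, b = rng.normal(size=2) / np.sqrt(ell)  # mildly soften high degrees
            y = sph_harm_y(ell, m, tg, pg)
            f += a * y.real
            if m > 0:
                f += b * y.imag
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def _harmonic_modulation(spec: ShellSpec, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Band-limited random function on S^2, normalized to max |f| ~= 1."""
    table = _modulation_table(spec.seed, spec.lmax)
    ti = np.clip(theta, 0, np.pi) / np.pi * (len(_THETA_GRID) - 1)
    pi_ = (np.clip(phi, -np.pi, np.pi) + np.pi) / (2 * np.pi) * (len(_PHI_GRID) - 1)
    t0 = np.clip(np.floor(ti).astype(int), 0, len(_THETA_GRID) - 2)
    p0 = np.clip(np.floor(pi_).astype(int), 0, len(_PHI_GRID) - 2)
    dt = ti - t0
    dp = pi_ - p0
    return (
        table[t0, p0] * (1 - dt) * (1 - dp)
        + table[t0 + 1, p0] * dt * (1 - dp)
        + table[t0, p0 + 1] * (1 - dt) * dp
        + table[t0 + 1, p0 + 1] * dt * dp
    )


def _polar_grids(shape, resolution):
    """(rho, unit direction angles grid helper) around the grid center."""
    center = (np.array(shape) - 1) / 2.0
    ax = [(np.arange(n) - c) * resolution for n, c in zip(shape, center)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    rho = np.sqrt(x * x + y * y + z * z)
    return rho, (x, y, z)


def surface_radius(spec: ShellSpec, theta, phi) -> np.ndarray:
    """Surface radius r(theta, phi) in mm along given directions."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if spec.deformation_amplitude == 0:
        return np.full(np.broadcast(theta, phi).shape, spec.base_radius)
    f = _harmonic_modulation(spec, theta, phi)
    return spec.base_radius * (1.0 + spec.deformation_amplitude * f)


def generate_shell(spec: ShellSpec) -> Shell:
    """Rasterize the shell on the GS grid and mesh its surface.

    The continuous signed field r(theta, phi) - rho is evaluated per voxel;
    its zero iso-surface (marching cubes) gives a smooth, accurate mesh even
    at modest grid resolution, avoiding the staircase bias of binary masks.
    """
    amp = spec.deformation_amplitude
    rmax = spec.base_radius * (1 + amp)
    half = int(np.ceil(rmax / spec.resolution)) + 3
    shape = (2 * half + 1,) * 3
    rho, (x, y, z) = _polar_grids(shape, spec.resolution)

    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, z / np.where(rho > 0, rho, 1), 1.0), -1, 1))
    phi = np.arctan2(y, x)

    if amp > 0:
        f = _harmonic_modulation(spec, theta, phi)
        rsurf = spec.base_radius * (1.0 + amp * f)
    else:
        rsurf = np.full_like(rho, spec.base_radius)
    field = rsurf - rho
    inside = field > 0

    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.0, spacing=(spec.resolution,) * 3
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return Shell(spec=spec, inside=inside, field=field,
                 spacing=(spec.resolution,) * 3, mesh=mesh)


def compute_sphericity_gs(volume: float, surface: float) -> float:
    """Sphericity of a closed shape from its volume and surface area.

    Parameters are in consistent units (cc and cm^2, or mm^3 and mm^2).
    Returns pi^(1/3) (6V)^(2/3) / A: 1 for a sphere, < 1 otherwise.
    """
    if volume <= 0 or surface <= 0:
        raise ValueError("volume and surface must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface)


def calibrate_amplitude(
    seed: int,
    target_sphericity: float,
    base_radius: float = 15.0,
    resolution: float = 1.5,
    lmax: int = 8,
    tol: float = 0.01,
    max_iter: int = 24,
) -> float:
    """Find the deformation amplitude giving a target sphericity (bisection).

    Sphericity decreases monotonically with amplitude for a fixed harmonic
    seed; amplitude and sphericity are both scale-free, so the result can be
    reused at any base radius.
    """
    if not (0 < target_sphericity <= 1):
        raise ValueError("target sphericity must be in (0, 1]")
    lo, hi = 0.0, 0.95

    def s_of(a: float) -> float:
        return generate_shell(
            ShellSpec(seed=seed, base_radius=base_radius,
                      deformation_amplitude=a, resolution=resolution, lmax=lmax)
        ).sphericity

    s_hi = s_of(hi)
    if s_hi > target_sphericity:  # even max deformation too round
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = s_of(mid)
        if abs(s - target_sphericity) < tol:
            return mid
        if s > target_sphericity:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
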
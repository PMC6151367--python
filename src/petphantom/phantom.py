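"""Assemble digital lesion phantoms: carve uptake compartments into a shell.

The rasterizer turns a :class:`~petphantom.shells.Shell` plus an
:class:`~petphantom.uptake.UptakeConfig` into an integer compartment label
map on the ground-truth grid (0 = background, 1..k = compartment index in
the config's ordering).  Compartment shapes per layout:

* concentric regions exploit the star-shaped geometry: the sub-level set
  {rho / r(theta, phi) <= t} holds exactly t^3 of the volume, so fraction
  targets convert to radial thresholds in closed form;
* focal blobs (off-center necrosis, hot foci) are spheres whose center and
  direction come from the config seed and whose radius matches the target
  volume fraction;
* wedges are angular sectors in azimuth.

Realized voxel fractions are then measured on the grid (the digital
counterpart of weighing each gel compartment) and stored back into the
effective config so that ground-truth indices reflect the lesion actually
rasterized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .shells import Shell, surface_radius
from .uptake import HOT_LAYOUTS, LesionGroundTruth, UptakeConfig


@dataclass
class Phantom:
    """A rasterized lesion in a uniform background, ready for simulation."""

    shell: Shell
    config: UptakeConfig  # realized fractions (voxel-measured)
    labels: np.ndarray  # 0 = background, 1..k compartments
    background: float  # MBq/cc
    spacing: tuple[float, float, float]

    def nominal_concentrations(self) -> np.ndarray:
        """Noise-free concentration volume on the GS grid."""
        lut = np.concatenate([[self.background], self.config.concentrations()])
        return lut[self.labels]

    def lesion_mask(self) -> np.ndarray:
        return self.labels > 0


def _unit(vec: np.ndarray) -> np.ndarray:
    return vec / np.linalg.norm(vec)


def _blob(center_mm, radius_mm, shape, spacing):
    c = (np.array(shape) - 1) / 2.0
    ax = [(np.arange(n) - cc) * s for n, cc, s in zip(shape, c, spacing)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    d2 = (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2
    return d2 <= radius_mm**2


def rasterize_compartments(shell: Shell, config: UptakeConfig) -> np.ndarray:
    """Label each GS voxel with its compartment (0 = background)."""
    inside = shell.inside
    spec = shell.spec
    labels = np.zeros(inside.shape, dtype=np.int16)
    conc = config.concentrations()
    fr = config.fractions()
    rng = np.random.default_rng(config.seed)
    layout = config.layout

    # index of each compartment in the config ordering (1-based labels)
    def idx_of(value_pos: int) -> int:
        return value_pos + 1

    if layout == "uniform":
        labels[inside] = 1
        return labels

    u = shell.radial_fraction()
    labels[inside] = idx_of(int(np.argmax(conc == config.c1)))  # fill with C1

    v_total_mm3 = abs(shell.mesh.volume)

    def _r_dir(direction: np.ndarray) -> float:
        theta = float(np.arccos(np.clip(direction[2], -1, 1)))
        phi = float(np.arctan2(direction[1], direction[0]))
        return float(surface_radius(spec, theta, phi)[0])

    def pick_direction(avoid: np.ndarray | None = None, n_cand: int = 24) -> np.ndarray:
        """Seeded direction with ample local radius (blobs must fit inside
        a strongly deformed shell); optionally repelled from `avoid`."""
        best, best_score = None, -np.inf
        for _ in range(n_cand):
            d = _unit(rng.normal(size=3))
            score = _r_dir(d)
            if avoid is not None:
                score -= 2.0 * spec.base_radius * max(0.0, float(d @ avoid))
            if score > best_score:
                best, best_score = d, score
        return best

    def place_blob(target_fraction: float, label: int, direction: np.ndarray,
                   center_t: float = 0.45) -> None:
        r_dir = _r_dir(direction)
        rb = (3.0 * target_fraction * v_total_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        rb = min(rb, 0.55 * r_dir)  # keep the blob inside the shell
        center = center_t * r_dir * direction
        blob = _blob(center, rb, inside.shape, shell.spacing) & inside
        labels[blob] = label

    if layout == "a":  # concentric necrotic core
        f0 = fr[0]
        labels[inside & (u <= f0 ** (1.0 / 3.0))] = 1
    elif layout == "b":  # off-center necrotic blob
        place_blob(fr[0], 1, pick_direction())
    elif layout == "c":  # necrotic azimuthal wedge
        c = (np.array(inside.shape) - 1) / 2.0
        ax = [(np.arange(n) - cc) * s for n, cc, s in zip(inside.shape, c, shell.spacing)]
        x, y, _ = np.meshgrid(*ax, indexing="ij")
        phi0 = rng.uniform(-np.pi, np.pi)
        dphi = np.angle(np.exp(1j * (np.arctan2(y, x) - phi0)))
        half_width = fr[0] * np.pi  # angular fraction ~ volume fraction
        labels[inside & (np.abs(dphi) <= half_width)] = 1
    elif layout == "d":  # single hot focus
        place_blob(fr[1], 2, pick_direction())
    elif layout == "e":  # two hot foci, roughly opposite
        d1 = pick_direction()
        d2 = pick_direction(avoid=d1)
        place_blob(fr[1] / 2, 2, d1)
        place_blob(fr[1] / 2, 2, d2)
    elif layout == "f":  # necrotic core + hot focus
        f0 = fr[0]
        labels[inside & (u <= f0 ** (1.0 / 3.0))] = 1
        place_blob(fr[2], 3, pick_direction())
    elif layout == "g":  # concentric: C0 core, C2 mid shell, C1 rim
        f0, _, f2 = fr
        t0 = f0 ** (1.0 / 3.0)
        t2 = (f0 + f2) ** (1.0 / 3.0)
        labels[inside & (u <= t2)] = 3
        labels[inside & (u <= t0)] = 1
    else:  # pragma: no cover
        raise ValueError(f"unhandled layout {layout!r}")
    return labels


def realized_config(labels: np.ndarray, config: UptakeConfig) -> UptakeConfig:
    """Replace target fractions with the voxel-measured ones."""
    k = len(config.fractions())
    counts = np.array([(labels == i + 1).sum() for i in range(k)], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty lesion rasterization")
    return dc_replace(config, volume_fractions=tuple(counts / total))


def build_phantom(shell: Shell, config: UptakeConfig, background: float) -> Phantom:
    """Rasterize compartments and bind the realized composition."""
    if background <= 0:
        raise ValueError("background concentration must be positive")
    labels = rasterize_compartments(shell, config)
    cfg = realized_config(labels, config)
    return Phantom(shell=shell, config=cfg, labels=labels,
                   background=background, spacing=shell.spacing)


def ground_truth(phantom: Phantom, lesion_id: str, shell_id: str,
                 seed: int, meta: dict | None = None) -> LesionGroundTruth:
    """Ground-truth record of a rasterized phantom (realized composition)."""
    return LesionGroundTruth.from_components(
        lesion_id=lesion_id,
        shell_id=shell_id,
        volume_cc=phantom.shell.volume_cc,
        sphericity=phantom.shell.sphericity,
        config=phantom.config,
        background=phantom.background,
        seed=seed,
        meta=meta,
    )
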
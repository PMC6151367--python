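"""Shared fixtures: small simulated lesions and digital solids."""

from __future__ import annotations

import numpy as np
import pytest

from petphantom import (
    AcquisitionSettings,
    ShellSpec,
    UptakeConfig,
    build_phantom,
    default_settings,
    generate_shell,
    ground_truth,
    simulate_acquisition,
)

#: one master seed shared by fixtures so the shell cache is reused
MASTER_SEED = 11


@pytest.fixture(scope="session")
def uniform_lesion():
    """A noiseless-signal lesion with uniform uptake, L/B = 10."""
    shell = generate_shell(
        ShellSpec(seed=3, base_radius=14.0, deformation_amplitude=0.3, resolution=1.0)
    )
    bg = 0.006
    cfg = UptakeConfig(layout="uniform", c1=10 * bg, volume_fractions=(1.0,))
    phantom = build_phantom(shell, cfg, background=bg)
    gt = ground_truth(phantom, "U1", "A", 3)
    return phantom, gt


@pytest.fixture(scope="session")
def het_lesion():
    """A heterogeneous lesion (necrotic core + hot focus)."""
    shell = generate_shell(
        ShellSpec(seed=5, base_radius=15.0, deformation_amplitude=0.4, resolution=1.0)
    )
    bg = 0.006
    cfg = UptakeConfig(layout="f", c1=0.06, volume_fractions=(0.1, 0.75, 0.15), seed=9)
    phantom = build_phantom(shell, cfg, background=bg)
    gt = ground_truth(phantom, "H1", "B", 5)
    return phantom, gt


@pytest.fixture(scope="session")
def noisy_image(het_lesion):
    phantom, gt = het_lesion
    return simulate_acquisition(phantom, default_settings(seed=MASTER_SEED)), gt


@pytest.fixture(scope="session")
def noiseless_image(uniform_lesion):
    phantom, gt = uniform_lesion
    settings = AcquisitionSettings(noise_scale=0.0, seed=0)
    return simulate_acquisition(phantom, settings), gt


@pytest.fixture()
def digital_sphere():
    """Binary sphere of radius 20 voxels on a unit grid."""
    n = 45
    c = (n - 1) / 2.0
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    return ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= 20.0**2
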